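"""End-to-end demo wiring every stage, with reproducible per-stage seeds."""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from statistics import median
from typing import Any

import numpy as np

from . import cohort, datasets, decompose, g4, haplotypes, ogm, screen, simulate
from .motifs import RepeatConfiguration, parse_runs

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Fan one global seed out to a stable per-stage seed (< 2**31)."""
    digest = hashlib.blake2s(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _case_config(case: str, allele: int, seed: int,
                 flank_length: int = 300) -> RepeatConfiguration:
    runs = parse_runs(datasets.case_configuration(case, allele),
                      allow_unknown=False)
    rng = np.random.default_rng(derive_seed(seed, f"flanks:{case}:{allele}"))
    return simulate.make_configuration(
        [(m, c) for m, c in runs], rng, flank_length=flank_length)


def decompose_case_read(case: str = "II-1", allele: int = 1,
                        seed: int = 0) -> decompose.Decomposition:
    """Build one error-free read from a clinical-table allele and decompose it."""
    cfg = _case_config(case, allele, seed)
    reads = simulate.simulate_reads((cfg, cfg), coverage=1, error_rate=0.0,
                                    seed=derive_seed(seed, f"read:{case}"))
    read = reads.reads[0]
    _, dec = decompose.decompose_read(
        read.sequence, cfg.left_anchor(), cfg.right_anchor(),
        motif_set=sorted({m for m, _ in cfg.runs}), read_id=read.read_id)
    return dec


def noisy_copy_recovery(case: str = "VIII-1", allele: int = 1,
                        n_reads: int = 20, error_rate: float = 0.08,
                        seed: int = 0) -> dict[str, Any]:
    """Recover the first-run copy number from noisy simulated spanning reads.

    Simulates ``n_reads`` spanning reads at the given error rate
    (substitution:insertion:deletion 60:20:20) from one clinical-table
    allele, decomposes each, and reports the median copy number of the first
    segment matching the allele's first motif.
    """
    cfg = _case_config(case, allele, seed)
    reads = simulate.simulate_reads((cfg, cfg), coverage=(n_reads + 1) // 2,
                                    error_rate=error_rate,
                                    seed=derive_seed(seed, f"reads:{case}"))
    motif_set = sorted({m for m, _ in cfg.runs})
    first_motif = cfg.runs[0][0]
    copies = []
    for read in list(reads)[:n_reads]:
        _, dec = decompose.decompose_read(
            read.sequence, cfg.left_anchor(), cfg.right_anchor(),
            motif_set=motif_set, read_id=read.read_id)
        seg = next((s for s in dec.segments if s.motif == first_motif), None)
        if seg is not None:
            copies.append(seg.copies)
    return {
        "case": case,
        "truth_copies": cfg.runs[0][1],
        "median_copies": float(median(copies)) if copies else float("nan"),
        "n_reads": len(copies),
        "read_length": len(cfg.sequence()),
    }


def run_demo(seed: int = 0, out: str | Path | None = None) -> dict[str, Any]:
    """Regenerate the pipeline's headline numbers from scratch.

    Runs simulate -> decompose -> screen/classify -> G4 -> OGM sizing ->
    haplotype sharing -> cohort statistics and returns a report dict.  The
    report's ``pinned`` section compares deterministic quantities against
    their published values; any mismatch sets ``ok`` to False (the CLI turns
    that into a non-zero exit status).
    """
    report: dict[str, Any] = {"seed": seed}

    # G4 propensity of the repeat motifs at 10 copies
    g4_scores = {m: g4.score_motif(m).score
                 for m in ("AAGGG", "AGGGC", "AAAGG", "AGAGG", "AAAAG")}
    report["g4_scores"] = g4_scores

    # configuration screen on a genotype table with the published counts
    table = simulate.simulate_genotype_table(
        datasets.screen_counts(), datasets.N_CASES, datasets.N_CONTROLS,
        seed=derive_seed(seed, "genotypes"))
    results = screen.ConfigurationScreen(table).fit()
    report["screen"] = {
        "rare_homozygous": sorted(results.rare_homozygous()),
        "aaagg_p_value": round(results.p_value("AAGGG/AAAGG"), 2),
        # NaN p-values (rows with a zero cell) serialize as null
        "rows": json.loads(results.rows.to_json(orient="records")),
    }

    # classification of the clinical-table genotypes
    clin = datasets.clinical_table()
    calls = {}
    for row in clin.itertuples(index=False):
        rec = simulate.GenotypeRecord(row.case, "case", "NA",
                                      row.allele1, None, row.allele2, None)
        calls[row.case] = screen.classify_genotype(rec).genotype_call
    report["classification"] = calls

    # decomposition: error-free exactness and noisy recovery
    dec = decompose_case_read("II-1", 1, seed)
    report["decomposition_exact"] = {"notation": dec.notation(),
                                     "copies": dec.segments[0].copies
                                     if dec.segments else None}
    report["decomposition_noisy"] = noisy_copy_recovery("VIII-1", 1, seed=seed)

    # optical-map sizing of a simulated heterozygous sample
    mols = simulate.simulate_ogm_molecules(
        (0, 980), n=400, noise_sd=50.0, seed=derive_seed(seed, "ogm"),
        reference=datasets.OGM_REFERENCE_BP)
    fit = ogm.RepeatSizeMixture(mols.distances,
                                reference=datasets.OGM_REFERENCE_BP).fit()
    report["ogm"] = {"k": fit.k, "allele_sizes": list(fit.allele_sizes),
                     "means_bp": [round(m, 1) for m in fit.means]}

    # haplotype sharing: published marker spans + planted-interval recovery
    A, B, C = (datasets.HAPLOTYPE_MARKERS_HG38[k] for k in "ABC")
    positions = np.arange(39_150_000, 39_380_001, 2000)
    hap = simulate.simulate_haplotypes(
        n_haps=12, markers=positions, carrier_rows=range(6),
        shared_interval=(B, C), anchor=(B + C) // 2,
        seed=derive_seed(seed, "haplotypes"))
    rec_interval = haplotypes.shared_interval(hap)
    report["haplotype"] = {
        "span_A_C_kb": haplotypes.span_kb(A, C),
        "span_B_C_kb": haplotypes.span_kb(B, C),
        "span_B_C_printed_kb": 66,   # published figure; computed span differs
        "recovered_span_kb": rec_interval.span_kb,
    }

    # cohort statistics
    aoo = cohort.summarize_numeric(clin["age_of_onset"])
    dd = cohort.summarize_numeric(clin["disease_duration"])
    rng = np.random.default_rng(derive_seed(seed, "sizes"))
    mu_a, sd_a, n_a = datasets.AAAGG_SIZE_CASES
    mu_b, sd_b, n_b = datasets.AAAGG_SIZE_CONTROLS
    sizes_cases = np.maximum(1, rng.normal(mu_a, sd_a, n_a))
    sizes_controls = np.maximum(1, rng.normal(mu_b, sd_b, n_b))
    _, p_sizes = cohort.compare_sizes(sizes_cases, sizes_controls,
                                      method="welch")
    report["cohort"] = {
        "age_of_onset": str(aoo),
        "disease_duration": str(dd),
        "aaagg_size_p": p_sizes,
    }

    # pinned deterministic targets
    pinned = {
        "g4_AAGGG": (g4_scores["AAGGG"], 2.00),
        "g4_AGGGC": (g4_scores["AGGGC"], 1.83),
        "g4_AAAGG": (g4_scores["AAAGG"], 0.94),
        "g4_AGAGG": (g4_scores["AGAGG"], 1.12),
        "g4_AAAAG": (g4_scores["AAAAG"], None),
        "screen_aaagg_p": (report["screen"]["aaagg_p_value"], 0.05),
        "decomposition_copies": (report["decomposition_exact"]["copies"], 1240),
        "span_A_C_kb": (report["haplotype"]["span_A_C_kb"], 207),
    }
    report["pinned"] = {k: {"computed": v[0], "expected": v[1]}
                        for k, v in pinned.items()}
    report["ok"] = all(v[0] == v[1] for v in pinned.values())

    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        (out / "demo_report.json").write_text(json.dumps(report, indent=2))
        logger.info("wrote %s", out / "demo_report.json")
    return report
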