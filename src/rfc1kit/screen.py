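"""Case/control configuration screen and pathogenicity classification.

Given a genotype table (two allele calls per sample, each a motif
configuration plus size), the screen tabulates homozygous expansion
genotypes and motifs found compound heterozygous with the common pathogenic
AAGGG expansion, per phenotype group, with an association test per row; the
classifier applies per-motif size rules to call each allele pathogenic,
benign or uncertain, and the genotype biallelic-pathogenic, carrier, benign
or uncertain.

Classification defaults (repeat units): AAAAG, AAGAG and AAAGGG are benign
at any size; AAGGG, ACAGG, AGGGC, AAGGC and AGAGG are pathogenic from 250
units (the smallest pathogenic expansion observed for the common motif);
AAAGG is benign unless very large (> 500 units).  A mixed-run allele is
pathogenic when any constituent pathogenic-motif run meets its own
threshold, or when its total G-rich size exceeds 500 units and it carries an
AAGGG interruption.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import parse_runs
from .simulate import GenotypeRecord, GenotypeTable

logger = logging.getLogger(__name__)

BENIGN_MOTIFS = frozenset({"AAAAG", "AAGAG", "AAAGGG"})
PATHOGENIC_MOTIFS = frozenset({"AAGGG", "ACAGG", "AGGGC", "AAGGC", "AGAGG"})

#: Alleles shorter than this (repeat units) are treated as non-expanded
#: reference alleles for tabulation purposes; the normal non-pathogenic
#: range at this locus tops out around 220 units and the reference AAAAG
#: allele is ~9-11 units.
MIN_EXPANDED_SIZE = 50


# ---------------------------------------------------------------------------
# association tests

def association_test(a: int, b: int, c: int, d: int,
                     method: str = "chisq") -> float:
    """Two-sided p-value for a 2x2 table [[a, b], [c, d]].

    ``chisq`` is the Pearson chi-square without continuity correction (1 df);
    ``fisher`` is the exact two-sided test summing hypergeometric
    probabilities no larger than the observed table's.
    """
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0).min() == 0) or (table.sum(axis=1).min() == 0):
        raise ValueError("zero margin: association test undefined")
    if method == "chisq":
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
    elif method == "fisher":
        _, p = stats.fisher_exact(table, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# tabulation

def _allele_label(config: str, size: int | None) -> tuple[str, bool]:
    """Reduce an allele to (dominant motif, is_expanded)."""
    runs = parse_runs(config, allow_unknown=True)
    known = [(m, c) for m, c in runs if c is not None]
    if known:
        motif = max(known, key=lambda r: r[1])[0]
        total = sum(c for _, c in known)
    else:
        motif = runs[0][0]
        total = None
    if size is not None:
        total = size if total is None else max(total, size)
    expanded = total is None or total >= MIN_EXPANDED_SIZE
    return motif, expanded


def _genotype_key(record: GenotypeRecord) -> tuple[str, str] | None:
    (c1, s1), (c2, s2) = record.alleles()
    m1, e1 = _allele_label(c1, s1)
    m2, e2 = _allele_label(c2, s2)
    if not (e1 or e2):
        return None                      # non-expanded reference genotype
    if m1 == m2:
        return (m1, m2)
    # orient compound genotypes: AAGGG first, then alphabetical
    if m2 == "AAGGG":
        m1, m2 = m2, m1
    elif m1 != "AAGGG":
        m1, m2 = sorted((m1, m2))
    return (m1, m2)


def tabulate_configurations(table: GenotypeTable,
                            method: str = "chisq") -> pd.DataFrame:
    """Count expansion genotypes per group, Table-style.

    Returns one row per observed genotype: homozygous rows labelled
    ``"MOTIF (hom)"`` and compound-heterozygous rows ``"M1/M2"``; columns
    ``case_count``, ``case_pct``, ``control_count``, ``control_pct`` and
    ``p_value`` (NaN where a group has zero carriers).  Percentages are
    count/group-size rounded to 1 decimal.
    """
    if not table.records:
        raise ValueError("empty genotype table")
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for rec in table.records:
        key = _genotype_key(rec)
        if key is None:
            continue
        row = counts.setdefault(key, {"case": 0, "control": 0})
        row[rec.group] += 1

    hom = sorted(k for k in counts if k[0] == k[1])
    het = sorted((k for k in counts if k[0] != k[1]),
                 key=lambda k: (-counts[k]["case"], -counts[k]["control"], k))
    rows = []
    for key in hom + het:
        m1, m2 = key
        label = f"{m1} (hom)" if m1 == m2 else f"{m1}/{m2}"
        a, c = counts[key]["case"], counts[key]["control"]
        p = np.nan
        if a > 0 and c > 0:
            p = association_test(a, table.n_cases - a,
                                 c, table.n_controls - c, method=method)
        rows.append({
            "label": label, "allele1": m1, "allele2": m2,
            "case_count": a,
            "case_pct": round(100 * a / table.n_cases, 1),
            "control_count": c,
            "control_pct": round(100 * c / table.n_controls, 1),
            "p_value": p,
        })
    return pd.DataFrame(rows)


def rare_homozygous_screen(report: pd.DataFrame, n_cases: int,
                           max_case_freq: float = 0.01) -> set[str]:
    """Motifs homozygous in >= 1 case, rare (< ``max_case_freq``) among
    cases, and absent in controls."""
    out = set()
    for row in report.itertuples(index=False):
        if (row.allele1 == row.allele2 and row.case_count >= 1
                and row.case_count / n_cases < max_case_freq
                and row.control_count == 0):
            out.add(row.allele1)
    return out


def compound_het_screen(report: pd.DataFrame,
                        partner: str = "AAGGG") -> set[str]:
    """Motifs seen compound heterozygous with ``partner`` in cases but
    absent in controls."""
    out = set()
    for row in report.itertuples(index=False):
        if (row.allele1 == partner and row.allele2 != partner
                and row.case_count >= 1 and row.control_count == 0):
            out.add(row.allele2)
    return out


# ---------------------------------------------------------------------------
# statsmodels-style screen wrapper

class ConfigurationScreen:
    """Case/control screen over a genotype table.

    ``ConfigurationScreen(table).fit()`` returns a :class:`ScreenResults`
    holding the per-genotype count table, association p-values and the
    candidate-motif screens.
    """

    def __init__(self, table: GenotypeTable, method: str = "chisq"):
        self.table = table
        self.method = method

    @classmethod
    def from_tsv(cls, path, method: str = "chisq") -> "ConfigurationScreen":
        return cls(GenotypeTable.from_tsv(path), method=method)

    def fit(self) -> "ScreenResults":
        rows = tabulate_configurations(self.table, method=self.method)
        return ScreenResults(rows, self.table.n_cases, self.table.n_controls,
                             self.method)


@dataclass
class ScreenResults:
    rows: pd.DataFrame
    n_cases: int
    n_controls: int
    method: str

    def rare_homozygous(self, max_case_freq: float = 0.01) -> set[str]:
        return rare_homozygous_screen(self.rows, self.n_cases, max_case_freq)

    def compound_het_with(self, partner: str = "AAGGG") -> set[str]:
        return compound_het_screen(self.rows, partner)

    def p_value(self, label: str) -> float:
        hit = self.rows[self.rows["label"] == label]
        if hit.empty:
            raise KeyError(label)
        return float(hit["p_value"].iloc[0])

    def summary(self) -> str:
        lines = [f"Configuration screen ({self.n_cases} cases, "
                 f"{self.n_controls} controls; {self.method})",
                 f"{'genotype':<18}{'cases':>12}{'controls':>14}{'p':>8}"]
        for r in self.rows.itertuples(index=False):
            p = ("-" if np.isnan(r.p_value)
                 else "ns" if round(r.p_value, 2) > 0.05
                 else f"{r.p_value:.2f}")
            lines.append(f"{r.label:<18}"
                         f"{f'{r.case_count} ({r.case_pct}%)':>12}"
                         f"{f'{r.control_count} ({r.control_pct}%)':>14}"
                         f"{p:>8}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# pathogenicity classification

@dataclass(frozen=True)
class ClassificationThresholds:
    pathogenic_min: int = 250        # smallest pathogenic expansion (units)
    aaagg_pathogenic_min: int = 500  # AAAGG is benign unless very large
    benign_motifs: frozenset = BENIGN_MOTIFS
    pathogenic_motifs: frozenset = PATHOGENIC_MOTIFS


@dataclass(frozen=True)
class PathogenicityCall:
    allele_calls: tuple[str, str]
    genotype_call: str
    rules: tuple[str, str]


def _classify_allele(runs: Sequence[tuple[str, int | None]],
                     th: ClassificationThresholds) -> tuple[str, str]:
    if len(runs) == 1:
        motif, size = runs[0]
        if motif in th.benign_motifs:
            return "benign", f"{motif} is benign at any size"
        if motif == "AAAGG":
            if size is None:
                return "uncertain", "AAAGG of unknown size"
            if size > th.aaagg_pathogenic_min:
                return "pathogenic", (f"AAAGG size {size} > "
                                      f"{th.aaagg_pathogenic_min}")
            return "benign", (f"AAAGG size {size} <= "
                              f"{th.aaagg_pathogenic_min}")
        if motif in th.pathogenic_motifs:
            if size is None:
                return "uncertain", f"{motif} of unknown size"
            if size >= th.pathogenic_min:
                return "pathogenic", f"{motif} size {size} >= {th.pathogenic_min}"
            return "benign", (f"{motif} size {size} below pathogenic "
                              f"minimum {th.pathogenic_min}")
        logger.warning("unknown motif %s: calling uncertain", motif)
        return "uncertain", f"unknown motif {motif}"

    # mixed-run allele
    sub = [_classify_allele([r], th) for r in runs]
    for (call, rule), (motif, _) in zip(sub, runs):
        if call == "pathogenic":
            return "pathogenic", f"constituent run: {rule}"
    g_rich = [c for m, c in runs
              if c is not None and (m in th.pathogenic_motifs or m == "AAAGG")]
    if (sum(g_rich) > th.aaagg_pathogenic_min
            and any(m == "AAGGG" for m, _ in runs)):
        return "pathogenic", (f"total G-rich size {sum(g_rich)} > "
                              f"{th.aaagg_pathogenic_min} with AAGGG interruption")
    if any(call == "uncertain" for call, _ in sub):
        return "uncertain", "constituent run of unknown size or motif"
    return "benign", "no constituent run meets a pathogenic threshold"


def classify_genotype(record: GenotypeRecord,
                      thresholds: ClassificationThresholds | None = None
                      ) -> PathogenicityCall:
    """Classify one sample's genotype.

    Per-allele calls are pathogenic/benign/uncertain by motif-specific size
    rules; the genotype is biallelic-pathogenic iff both alleles are
    pathogenic, carrier when exactly one is, uncertain when none is but an
    allele could not be resolved, and benign otherwise.  Deterministic and
    symmetric in allele order.
    """
    th = thresholds or ClassificationThresholds()
    calls, rules = [], []
    for config, size in record.alleles():
        runs = parse_runs(config, allow_unknown=True)
        if len(runs) == 1 and runs[0][1] is None:
            runs = [(runs[0][0], size)]
        call, rule = _classify_allele(runs, th)
        calls.append(call)
        rules.append(rule)
    n_path = calls.count("pathogenic")
    if n_path == 2:
        genotype = "biallelic-pathogenic"
    elif n_path == 1:
        genotype = "carrier"
    elif "uncertain" in calls:
        genotype = "uncertain"
    else:
        genotype = "benign"
    return PathogenicityCall(tuple(calls), genotype, tuple(rules))


def classify_table(table: GenotypeTable,
                   thresholds: ClassificationThresholds | None = None
                   ) -> pd.DataFrame:
    rows = []
    for rec in table.records:
        call = classify_genotype(rec, thresholds)
        rows.append({"sample_id": rec.sample_id, "group": rec.group,
                     "allele1_call": call.allele_calls[0],
                     "allele2_call": call.allele_calls[1],
                     "genotype_call": call.genotype_call})
    return pd.DataFrame(rows)
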