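"""Synthetic-data generators with known ground truth.

Every input the analysis modules consume can be generated here under a fixed
seed: diploid repeat alleles and noisy long reads over them, case/control
genotype tables, optical-mapping intermarker distances, and phased haplotype
matrices with a planted shared ancestral segment.  All generators are
deterministic given their seed.

The read simulator emulates targeted long-read sequencing of an expanded
repeat locus: reads alternate between the two alleles, errors are i.i.d. per
base with a configurable substitution:insertion:deletion mix (default
60:20:20, an indel-rich nanopore-like profile), a configurable fraction of
reads is truncated inside the tract so that it covers only one flank, and
orientation is random.  It does not model basecaller-specific homopolymer
error structure or signal-level artefacts.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import (
    DNA_ALPHABET,
    ConfigurationError,
    RepeatConfiguration,
    build_allele_sequence,
    format_runs,
    reverse_complement,
)

_BASES = "ACGT"

GENOTYPE_TSV_COLUMNS = (
    "sample_id", "group", "ancestry",
    "allele1_config", "allele1_size", "allele2_config", "allele2_size",
)


# ---------------------------------------------------------------------------
# flanks and alleles

def random_flanks(rng: np.random.Generator, tract: str, length: int = 300,
                  k: int = 15, max_tries: int = 200) -> tuple[str, str]:
    """Draw random flanking sequences sharing no k-mer with the repeat tract.

    Anchor uniqueness is what makes tract location unambiguous; rejection
    sampling almost never loops because a random 300-mer rarely contains a
    15-mer from a low-complexity G-rich tract.
    """
    tract_kmers = {tract[i:i + k] for i in range(len(tract) - k + 1)}
    flanks = []
    for _ in range(2):
        for _ in range(max_tries):
            f = "".join(rng.choice(list(_BASES), size=length))
            if not any(f[i:i + k] in tract_kmers for i in range(len(f) - k + 1)):
                flanks.append(f)
                break
        else:  # pragma: no cover - practically unreachable
            raise RuntimeError("could not draw a flank free of tract k-mers")
    return flanks[0], flanks[1]


def make_configuration(runs: Sequence[tuple[str, int]],
                       rng: np.random.Generator | None = None,
                       flank_length: int = 300) -> RepeatConfiguration:
    """Build a configuration with random anchor-unique flanks."""
    rng = rng or np.random.default_rng(0)
    tract = "".join(m * c for m, c in runs)
    left, right = random_flanks(rng, tract, length=flank_length)
    return RepeatConfiguration(tuple(runs), left, right)


def make_diploid(runs1: Sequence[tuple[str, int]],
                 runs2: Sequence[tuple[str, int]],
                 rng: np.random.Generator | None = None,
                 flank_length: int = 300
                 ) -> tuple[RepeatConfiguration, RepeatConfiguration]:
    """Two alleles of one locus: different tracts, the same flanks."""
    rng = rng or np.random.default_rng(0)
    tract = ("".join(m * c for m, c in runs1)
             + "".join(m * c for m, c in runs2))
    left, right = random_flanks(rng, tract, length=flank_length)
    return (RepeatConfiguration(tuple(runs1), left, right),
            RepeatConfiguration(tuple(runs2), left, right))


# ---------------------------------------------------------------------------
# long reads

@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    source_allele: int
    spans_tract: bool
    strand: str


@dataclass
class ReadSet:
    reads: list[SimulatedRead]
    error_rate: float
    seed: int

    def __iter__(self):
        return iter(self.reads)

    def __len__(self):
        return len(self.reads)

    def to_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        records = [SeqRecord(Seq(r.sequence), id=r.read_id, description="")
                   for r in self.reads]
        SeqIO.write(records, str(path), "fasta")

    def to_fastq(self, path: str | Path) -> None:
        """Write FASTQ with a uniform quality derived from the error rate."""
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        if self.error_rate > 0:
            q = int(round(-10 * np.log10(self.error_rate)))
        else:
            q = 60
        q = max(2, min(60, q))
        records = []
        for r in self.reads:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [q] * len(r.sequence)
            records.append(rec)
        SeqIO.write(records, str(path), "fastq")


def _mutate(seq: str, rate: float, mix: tuple[float, float, float],
            rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    psub, pins, pdel = mix
    total = psub + pins + pdel
    psub, pins = psub / total, pins / total
    out: list[str] = []
    hit = rng.random(len(seq)) < rate
    kind = rng.random(len(seq))
    extra = rng.integers(0, 4, size=len(seq))
    for i, b in enumerate(seq):
        if not hit[i]:
            out.append(b)
            continue
        if kind[i] < psub:
            out.append(_BASES[(_BASES.index(b) + 1 + extra[i] % 3) % 4])
        elif kind[i] < psub + pins:
            out.append(b)
            out.append(_BASES[extra[i]])
        # else: deletion, emit nothing
    return "".join(out)


def simulate_reads(alleles: Sequence[str | RepeatConfiguration],
                   coverage: int = 20,
                   error_rate: float = 0.0,
                   truncate_frac: float = 0.0,
                   seed: int = 0,
                   error_mix: tuple[float, float, float] = (0.6, 0.2, 0.2),
                   ) -> ReadSet:
    """Simulate long reads over a pair of alleles.

    ``coverage`` reads are drawn from each allele, alternating.  A read is
    truncated (with probability ``truncate_frac``) at a uniform point inside
    the repeat tract, keeping one flank, so that it no longer spans the
    tract.  Each read is reverse complemented with probability 0.5.

    Identical arguments produce byte-identical output.
    """
    if len(alleles) != 2:
        raise ValueError("alleles must be a pair")
    if not 0 <= error_rate < 0.3:
        raise ValueError("error_rate must be in [0, 0.3)")
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    seqs: list[str] = []
    tract_bounds: list[tuple[int, int]] = []
    for a in alleles:
        if isinstance(a, RepeatConfiguration):
            seqs.append(a.sequence())
            tract_bounds.append((len(a.left_flank),
                                 len(a.left_flank) + len(a.tract())))
        else:
            s = str(a).upper()
            if not s:
                raise ValueError("empty allele sequence")
            seqs.append(s)
            # without run structure, treat the middle half as tract
            tract_bounds.append((len(s) // 4, 3 * len(s) // 4))

    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for i in range(2 * coverage):
        allele = i % 2
        seq = seqs[allele]
        lo, hi = tract_bounds[allele]
        spans = True
        if truncate_frac > 0 and rng.random() < truncate_frac:
            spans = False
            cut = int(rng.integers(lo + 1, hi)) if hi > lo + 1 else lo + 1
            if rng.random() < 0.5:
                seq = seq[:cut]          # keeps left flank
            else:
                seq = seq[cut:]          # keeps right flank
        seq = _mutate(seq, error_rate, error_mix, rng)
        strand = "+"
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
            strand = "-"
        reads.append(SimulatedRead(
            read_id=f"read_{i:04d}_a{allele}",
            sequence=seq,
            source_allele=allele,
            spans_tract=spans,
            strand=strand,
        ))
    return ReadSet(reads=reads, error_rate=error_rate, seed=seed)


# ---------------------------------------------------------------------------
# genotype tables

@dataclass(frozen=True)
class GenotypeRecord:
    sample_id: str
    group: str                       # "case" | "control"
    ancestry: str
    allele1_config: str              # motif or (MOTIF)count notation
    allele1_size: int | None
    allele2_config: str
    allele2_size: int | None

    def alleles(self) -> tuple[tuple[str, int | None], tuple[str, int | None]]:
        return ((self.allele1_config, self.allele1_size),
                (self.allele2_config, self.allele2_size))


@dataclass
class GenotypeTable:
    records: list[GenotypeRecord]
    n_cases: int
    n_controls: int

    def __post_init__(self):
        if len(self.records) != self.n_cases + self.n_controls:
            raise ValueError("record count must equal n_cases + n_controls")
        for r in self.records:
            if r.group not in ("case", "control"):
                raise ValueError(f"bad group {r.group!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records],
                            columns=list(GENOTYPE_TSV_COLUMNS))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"allele1_size": "Int64",
                                                "allele2_size": "Int64"})
        records = []
        for row in df.itertuples(index=False):
            records.append(GenotypeRecord(
                sample_id=str(row.sample_id), group=row.group,
                ancestry=str(row.ancestry),
                allele1_config=row.allele1_config,
                allele1_size=None if pd.isna(row.allele1_size) else int(row.allele1_size),
                allele2_config=row.allele2_config,
                allele2_size=None if pd.isna(row.allele2_size) else int(row.allele2_size),
            ))
        n_cases = sum(r.group == "case" for r in records)
        return cls(records, n_cases, len(records) - n_cases)


@dataclass(frozen=True)
class GenotypeSpec:
    """Requested count of one genotype per group.

    ``allele1``/``allele2`` are motif labels; the generator draws sizes from
    per-motif distributions.
    """
    allele1: str
    allele2: str
    n_cases: int
    n_controls: int
    ancestry: str = "European"


#: Expansion-size distributions (repeat units) used when a genotype table is
#: simulated: mean/SD per motif, optionally split by phenotype group.  The
#: AAAGG values are the observed CANVAS-patient versus control distributions;
#: novel G-rich pathogenic motifs share one distribution (892 +/- 247); benign
#: motifs sit in the normal non-expanded range.
DEFAULT_SIZE_PARAMS: dict = {
    "AAGGG": (1000, 250),
    "AAAGG": {"case": (979, 257), "control": (238, 142)},
    "AAGGC": (892, 247),
    "AGGGC": (892, 247),
    "AGAGG": (892, 247),
    "ACAGG": (892, 247),
    "ACGGG": (50, 5),
    "AAAAG": (120, 60),
    "AAGAG": (120, 60),
    "AAAGGG": (120, 60),
}

#: The benign reference allele (non-expanded poly-A-adjacent AAAAG run of
#: 9-11 units) assigned to samples not named in the frequency spec.
REFERENCE_ALLELE_MOTIF = "AAAAG"
REFERENCE_ALLELE_RANGE = (9, 11)


def _draw_size(motif: str, group: str, params: Mapping,
               rng: np.random.Generator) -> int:
    p = params.get(motif, (900, 250))
    if isinstance(p, Mapping):
        p = p.get(group, next(iter(p.values())))
    mean, sd = p
    return max(1, int(round(rng.normal(mean, sd))))


def simulate_genotype_table(frequency_spec: Sequence[GenotypeSpec],
                            n_cases: int = 893,
                            n_controls: int = 8107,
                            seed: int = 0,
                            size_params: Mapping | None = None,
                            ) -> GenotypeTable:
    """Emit a genotype table with exactly the requested genotype counts.

    Samples not covered by the spec receive the benign reference genotype
    (two small AAAAG alleles).  Sizes for expansion alleles are drawn from
    truncated normal distributions per motif (``size_params`` overrides
    :data:`DEFAULT_SIZE_PARAMS`).
    """
    params = dict(DEFAULT_SIZE_PARAMS)
    if size_params:
        params.update(size_params)
    need_cases = sum(s.n_cases for s in frequency_spec)
    need_controls = sum(s.n_controls for s in frequency_spec)
    if need_cases > n_cases or need_controls > n_controls:
        raise ValueError("requested genotype counts exceed group sizes")

    rng = np.random.default_rng(seed)
    records: list[GenotypeRecord] = []
    counters = {"case": 0, "control": 0}

    def add(group: str, spec: GenotypeSpec | None):
        counters[group] += 1
        sid = f"{group}_{counters[group]:05d}"
        if spec is None:
            lo, hi = REFERENCE_ALLELE_RANGE
            s1 = int(rng.integers(lo, hi + 1))
            s2 = int(rng.integers(lo, hi + 1))
            records.append(GenotypeRecord(sid, group, "European",
                                          REFERENCE_ALLELE_MOTIF, s1,
                                          REFERENCE_ALLELE_MOTIF, s2))
        else:
            records.append(GenotypeRecord(
                sid, group, spec.ancestry,
                spec.allele1, _draw_size(spec.allele1, group, params, rng),
                spec.allele2, _draw_size(spec.allele2, group, params, rng),
            ))

    for group, total in (("case", n_cases), ("control", n_controls)):
        for spec in frequency_spec:
            for _ in range(spec.n_cases if group == "case" else spec.n_controls):
                add(group, spec)
        while counters[group] < total:
            add(group, None)
    return GenotypeTable(records, n_cases, n_controls)


# ---------------------------------------------------------------------------
# optical-mapping intermarker distances

@dataclass
class MoleculeDistances:
    distances: np.ndarray
    truth_means: tuple[float, float] | None
    seed: int

    def to_file(self, path: str | Path) -> None:
        np.savetxt(path, self.distances, fmt="%.2f")

    @classmethod
    def from_file(cls, path: str | Path) -> "MoleculeDistances":
        return cls(np.loadtxt(path, ndmin=1), None, -1)


def simulate_ogm_molecules(allele_sizes: tuple[int, int],
                           n: int = 400,
                           noise_sd: float = 50.0,
                           seed: int = 0,
                           reference: float = 6858.0,
                           motif_len: int = 5) -> MoleculeDistances:
    """Simulate intermarker distances of labelled molecules over the locus.

    Each allele contributes half the molecules; a molecule's distance is
    ``reference + motif_len * allele_size`` plus Gaussian measurement noise.
    """
    if n < 2:
        raise ValueError("need at least 2 molecules")
    if min(allele_sizes) < 0:
        raise ValueError("allele sizes must be >= 0")
    rng = np.random.default_rng(seed)
    means = tuple(reference + motif_len * s for s in allele_sizes)
    counts = (n // 2, n - n // 2)
    parts = [rng.normal(mu, noise_sd, size=c) if noise_sd > 0
             else np.full(c, mu)
             for mu, c in zip(means, counts)]
    distances = np.concatenate(parts)
    return MoleculeDistances(distances=distances, truth_means=means, seed=seed)


# ---------------------------------------------------------------------------
# haplotype matrices

@dataclass
class HaplotypeMatrix:
    """Phased binary alleles at ordered markers for a set of haplotypes."""

    positions: np.ndarray            # strictly increasing bp coordinates
    alleles: np.ndarray              # (n_haps, n_markers) of {0,1}
    carrier_rows: frozenset[int]
    anchor: int                      # bp coordinate of the repeat locus
    shared_interval: tuple[int, int] | None = None   # planted truth (bp)
    recombinant: tuple[int, int] | None = None       # planted (row, marker idx)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.ndim != 2 or self.alleles.shape[1] != len(self.positions):
            raise ValueError("alleles must be (n_haps, n_markers)")
        if not self.positions[0] <= self.anchor <= self.positions[-1]:
            raise ValueError("anchor must lie within the marker range")
        self.carrier_rows = frozenset(int(r) for r in self.carrier_rows)
        if any(not 0 <= r < self.alleles.shape[0] for r in self.carrier_rows):
            raise ValueError("carrier row out of range")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.alleles, columns=self.positions)
        df.insert(0, "carrier", [int(i in self.carrier_rows)
                                 for i in range(self.alleles.shape[0])])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, anchor: int) -> "HaplotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        carriers = frozenset(int(i) for i, c in enumerate(df["carrier"]) if c)
        positions = np.array([int(c) for c in df.columns[1:]])
        return cls(positions, df.iloc[:, 1:].to_numpy(dtype=np.uint8),
                   carriers, anchor)


def simulate_haplotypes(n_haps: int,
                        markers: Sequence[int],
                        carrier_rows: Iterable[int],
                        shared_interval: tuple[int, int],
                        background_mismatch_rate: float = 0.5,
                        seed: int = 0,
                        anchor: int | None = None,
                        recombinant: tuple[int, int] | None = None,
                        force_boundaries: bool = True) -> HaplotypeMatrix:
    """Plant a shared ancestral segment into an otherwise random matrix.

    Carrier rows are copies of one core haplotype at every marker inside
    ``shared_interval`` (bp); outside it, and for non-carriers everywhere,
    each allele is the core value flipped independently with probability
    ``background_mismatch_rate``.  With ``force_boundaries`` (and >= 2
    carriers) the markers immediately flanking the interval are forced
    discordant among carriers, so the planted interval is recovered exactly.

    ``recombinant=(row, marker_index)`` converts one carrier into a
    recombinant that departs from the core haplotype from that marker
    outward (away from the anchor), forced discordant at the switch marker.
    """
    carriers = sorted(int(r) for r in carrier_rows)
    if not carriers:
        raise ValueError("carrier set must not be empty")
    positions = np.asarray(markers, dtype=np.int64)
    m = len(positions)
    start, end = shared_interval
    if anchor is None:
        anchor = (start + end) // 2
    if not (start <= anchor <= end):
        raise ValueError("anchor must lie inside the shared interval")
    if not (positions[0] <= start and end <= positions[-1]):
        raise ValueError("shared interval must lie within the marker range")

    rng = np.random.default_rng(seed)
    core = rng.integers(0, 2, size=m, dtype=np.uint8)
    inside = (positions >= start) & (positions <= end)
    alleles = np.empty((n_haps, m), dtype=np.uint8)
    for row in range(n_haps):
        flips = (rng.random(m) < background_mismatch_rate).astype(np.uint8)
        if row in carriers:
            flips[inside] = 0
        alleles[row] = core ^ flips

    if force_boundaries and len(carriers) >= 2:
        idx_inside = np.flatnonzero(inside)
        if idx_inside.size:
            for j in (idx_inside[0] - 1, idx_inside[-1] + 1):
                if 0 <= j < m:
                    alleles[carriers[0], j] = 1 - core[j]
                    for r in carriers[1:]:
                        alleles[r, j] = core[j]

    if recombinant is not None:
        row, k = recombinant
        if row not in carriers:
            raise ValueError("recombinant row must be a carrier")
        ai = int(np.searchsorted(positions, anchor))
        rand = rng.integers(0, 2, size=m, dtype=np.uint8)
        if positions[k] < anchor:
            alleles[row, :k + 1] = core[:k + 1] ^ rand[:k + 1]
        else:
            alleles[row, k:] = core[k:] ^ rand[k:]
        alleles[row, k] = 1 - core[k]
        del ai

    return HaplotypeMatrix(positions, alleles, frozenset(carriers), anchor,
                           shared_interval=(start, end),
                           recombinant=recombinant)
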