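"""Reference data for the RFC1 repeat locus.

Small published summary tables used as inputs and regression anchors: the
clinical table of the 14 patients carrying novel pathogenic repeat
configurations, the case/control configuration counts from the 100,000
Genomes screen (893 ataxia cases, 8107 controls), locus constants (the
non-expanded optical-map intermarker distance, the hg38 coordinates of the
haplotype markers flanking the shared ancestral segment), and the published
G4 propensity scores of the repeat motifs at 10 copies.
"""
from __future__ import annotations

import pandas as pd

from .simulate import GenotypeSpec

#: Screened cohort sizes (adult-onset ataxia cases vs non-neurological controls).
N_CASES = 893
N_CONTROLS = 8107

#: Optical mapping: intermarker distance of a non-expanded allele (bp).
OGM_REFERENCE_BP = 6858

#: hg38 chr4 coordinates of the haplotype markers delimiting the shared
#: ancestral segment: A (rs148316325), B (rs2066782), C (rs6851075).
HAPLOTYPE_MARKERS_HG38 = {"A": 39_158_847, "B": 39_302_305, "C": 39_366_034}

#: AAAGG expansion sizes (repeat units), mean/SD/group size: CANVAS patients
#: carrying a compound AAGGG/AAAGG genotype versus controls with the same
#: genotype.
AAAGG_SIZE_CASES = (979, 257, 5)
AAAGG_SIZE_CONTROLS = (238, 142, 8)

#: Published G4 propensity scores of RFC1 motifs at 10 copies (window 20,
#: threshold 1.5).  AAAAG forms no putative G4.  The AAGGC row is omitted:
#: its published value (1.82) is not reproducible from the stated scoring
#: parameters (run-based scoring yields 0.76; see docs/methods.md).
G4_REFERENCE_SCORES = {
    "AAGGG": 2.00,
    "AGGGC": 1.83,
    "AAAGG": 0.94,
    "AGAGG": 1.12,
    "AAAAG": None,
}


def screen_counts() -> list[GenotypeSpec]:
    """Case/control genotype counts of the published configuration screen.

    Two rare homozygous expansion genotypes and seven motifs found compound
    heterozygous with the common pathogenic AAGGG expansion.
    """
    return [
        GenotypeSpec("ACAGG", "ACAGG", 1, 0, ancestry="East Asian"),
        GenotypeSpec("AAGGC", "AAGGC", 1, 0, ancestry="South Asian"),
        GenotypeSpec("AAGGG", "AAAAG", 21, 248),
        GenotypeSpec("AAGGG", "AAAGGG", 5, 32),
        GenotypeSpec("AAGGG", "AAGAG", 3, 16),
        GenotypeSpec("AAGGG", "AAAGG", 10, 47),
        GenotypeSpec("AAGGG", "ACGGG", 1, 0),
        GenotypeSpec("AAGGG", "AGAGG", 1, 0),
        GenotypeSpec("AAGGG", "AGGGC", 1, 0),
    ]


_CLINICAL_ROWS = [
    # case, allele1, allele2, sex, phenotype, age_of_onset, disease_duration
    ("I-1",    "(AAGGG)510(AAGGC)880", "(AAGGG)940(AAGGC)900", "F", "CANVAS", 24, 17),
    ("I-2",    "(AAGGG)n(AAGGC)n",     "(AAGGG)n(AAGGC)n",     "F", "Sensory neuropathy + cough", 34, 8),
    ("II-1",   "(AGGGC)1240",          "(AAGGG)930",           "M", "Sensory neuropathy + vestibular dysfunction", 53, 11),
    ("III-1",  "(AGGGC)3200",          "(AAGGG)1000",          "M", "CANVAS", 71, 12),
    ("IV-1",   "(AGGGC)1875",          "(AAGGG)500",           "M", "CANVAS", 41, 34),
    ("V-1",    "(AGGGC)n",             "(AAGGG)n",             "F", "Sensory neuropathy + cough", 60, 13),
    ("V-2",    "(AGGGC)n",             "(AAGGG)n",             "F", "Sensory neuropathy", 40, 20),
    ("VI-1",   "(AGGGC)n",             "(AAGGG)n",             "F", "Sensory ganglionopathy + cough", 62, 23),
    ("VII-1",  "(AAAGG)470(AGAGG)470", "(AAGGG)1140",          "F", "CANVAS", 50, 24),
    ("VIII-1", "(AAAGG)610(AAGGG)390", "(AAGGG)1100",          "M", "CANVAS", 55, 20),
    ("IX-1",   "(AAGGG)700(AAAGG)200", "(AAGGG)1170",          "M", "CANVAS", 45, 31),
    ("X-1",    "(AAAGG)980",           "(AAGGG)1010",          "M", "CANVAS", 58, 15),
    ("XI-1",   "(AAAGG)800",           "(AAGGG)500",           "F", "Sensory ganglionopathy + cough", 73, 3),
    ("XII-1",  "(AAAGG)600",           "(AAGGG)390",           "M", "Sensory ganglionopathy + cough", 56, 10),
]


def clinical_table() -> pd.DataFrame:
    """Clinical/genotype table of the 14 patients with novel pathogenic
    configurations (allele notation ``(MOTIF)copies``; ``n`` = unsized)."""
    return pd.DataFrame(
        _CLINICAL_ROWS,
        columns=["case", "allele1", "allele2", "sex", "phenotype",
                 "age_of_onset", "disease_duration"],
    )


def case_configuration(case: str, allele: int = 1) -> str:
    """Configuration notation of one clinical-table allele."""
    df = clinical_table()
    row = df[df["case"] == case]
    if row.empty:
        raise KeyError(case)
    return str(row[f"allele{allele}"].iloc[0])
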