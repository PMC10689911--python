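import numpy as np
import pytest

from rfc1kit import RepeatConfiguration, make_configuration, make_diploid


@pytest.fixture
def case_viii1_allele1():
    """Case VIII-1 allele 1: (AAAGG)610(AAGGG)390 with 300 bp unique flanks."""
    rng = np.random.default_rng(2024)
    return make_configuration([("AAAGG", 610), ("AAGGG", 390)], rng)


@pytest.fixture
def small_het_configs():
    """A small compound-heterozygous genotype for fast decomposition tests."""
    rng = np.random.default_rng(7)
    return make_diploid([("AAAGG", 61), ("AAGGG", 39)],
                        [("AAGGG", 110)], rng)
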