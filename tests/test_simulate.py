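import numpy as np
import pytest

from rfc1kit import (
    GenotypeSpec,
    make_configuration,
    reverse_complement,
    simulate_genotype_table,
    simulate_haplotypes,
    simulate_ogm_molecules,
    simulate_reads,
)
from rfc1kit.datasets import screen_counts


def _normalized(read):
    return (reverse_complement(read.sequence) if read.strand == "-"
            else read.sequence)


class TestReadSimulator:
    def test_zero_noise_reads_contain_the_exact_tract(self, small_het_configs):
        a1, a2 = small_het_configs
        reads = simulate_reads((a1, a2), coverage=4, error_rate=0.0, seed=1)
        assert len(reads) == 8
        for read in reads:
            truth = (a1, a2)[read.source_allele]
            assert read.spans_tract
            assert _normalized(read) == truth.sequence()

    def test_same_seed_gives_byte_identical_readsets(self, small_het_configs):
        r1 = simulate_reads(small_het_configs, coverage=5, error_rate=0.08,
                            truncate_frac=0.3, seed=42)
        r2 = simulate_reads(small_het_configs, coverage=5, error_rate=0.08,
                            truncate_frac=0.3, seed=42)
        assert r1.reads == r2.reads
        r3 = simulate_reads(small_het_configs, coverage=5, error_rate=0.08,
                            truncate_frac=0.3, seed=43)
        assert r1.reads != r3.reads

    def test_substitution_count_is_binomial(self):
        # substitutions only (length-preserving), so the Hamming distance to
        # the source counts the edits exactly
        rng = np.random.default_rng(0)
        allele = "".join(rng.choice(list("ACGT"), size=1000))
        reads = simulate_reads((allele, allele), coverage=5, error_rate=0.08,
                               seed=11, error_mix=(1.0, 0.0, 0.0))
        for read in reads:
            seq = _normalized(read)
            assert len(seq) == 1000
            edits = sum(a != b for a, b in zip(seq, allele))
            sd = np.sqrt(1000 * 0.08 * 0.92)
            assert abs(edits - 80) <= 3 * sd

    def test_truncated_reads_keep_exactly_one_flank(self, small_het_configs):
        a1, _ = small_het_configs
        reads = simulate_reads((a1, a1), coverage=30, error_rate=0.0,
                               truncate_frac=1.0, seed=3)
        for read in reads:
            assert not read.spans_tract
            seq = _normalized(read)
            has_left = a1.left_flank in seq
            has_right = a1.right_flank in seq
            assert has_left != has_right

    def test_bad_parameters_raise(self, small_het_configs):
        with pytest.raises(ValueError):
            simulate_reads(("", "ACGT"), coverage=1)
        with pytest.raises(ValueError):
            simulate_reads(small_het_configs, coverage=1, error_rate=0.5)

    def test_fastq_roundtrip(self, tmp_path, small_het_configs):
        from Bio import SeqIO
        reads = simulate_reads(small_het_configs, coverage=2,
                               error_rate=0.05, seed=9)
        path = tmp_path / "reads.fastq"
        reads.to_fastq(path)
        records = list(SeqIO.parse(str(path), "fastq"))
        assert [r.id for r in records] == [r.read_id for r in reads]
        assert records[0].letter_annotations["phred_quality"][0] == 13


class TestGenotypeTableGenerator:
    def test_requested_counts_are_emitted_exactly(self):
        spec = [GenotypeSpec("AAGGG", "AAAGG", 10, 47),
                GenotypeSpec("ACAGG", "ACAGG", 1, 0)]
        table = simulate_genotype_table(spec, n_cases=100, n_controls=500,
                                        seed=0)
        df = table.to_frame()
        assert len(df) == 600
        key = df.allele1_config + "/" + df.allele2_config
        cases = df[df.group == "case"]
        controls = df[df.group == "control"]
        assert (key[cases.index] == "AAGGG/AAAGG").sum() == 10
        assert (key[controls.index] == "AAGGG/AAAGG").sum() == 47
        assert (key[cases.index] == "ACAGG/ACAGG").sum() == 1
        assert (key[controls.index] == "ACAGG/ACAGG").sum() == 0

    def test_empty_spec_gives_all_reference_genotypes(self):
        table = simulate_genotype_table([], n_cases=5, n_controls=5, seed=1)
        for rec in table.records:
            assert rec.allele1_config == rec.allele2_config == "AAAAG"
            assert rec.allele1_size <= 11 and rec.allele2_size <= 11

    def test_counts_exceeding_group_size_raise(self):
        with pytest.raises(ValueError):
            simulate_genotype_table([GenotypeSpec("AAGGG", "AAAAG", 10, 0)],
                                    n_cases=5, n_controls=5)

    def test_size_distributions_recovered_within_three_se(self):
        spec = [GenotypeSpec("AAGGG", "AAAGG", 200, 200)]
        table = simulate_genotype_table(spec, n_cases=250, n_controls=250,
                                        seed=5)
        df = table.to_frame()
        aaagg = df[df.allele2_config == "AAAGG"]
        for group, mean, sd in (("case", 979, 257), ("control", 238, 142)):
            sizes = aaagg[aaagg.group == group].allele2_size.astype(float)
            se = sd / np.sqrt(len(sizes))
            assert abs(sizes.mean() - mean) <= 3 * se

    def test_tsv_roundtrip(self, tmp_path):
        table = simulate_genotype_table(screen_counts(), n_cases=50,
                                        n_controls=400, seed=2)
        path = tmp_path / "genotypes.tsv"
        table.to_tsv(path)
        back = type(table).from_tsv(path)
        assert back.to_frame().equals(table.to_frame())


class TestOgmSimulator:
    def test_noise_free_distances_hit_the_truth_means_only(self):
        mols = simulate_ogm_molecules((0, 980), n=10, noise_sd=0.0, seed=0)
        assert set(np.round(mols.distances, 6)) == {6858.0, 11758.0}
        assert mols.truth_means == (6858.0, 11758.0)

    def test_homozygous_sample_is_unimodal(self):
        mols = simulate_ogm_molecules((0, 0), n=100, noise_sd=40.0, seed=1)
        assert abs(mols.distances.mean() - 6858) < 3 * 40 / 10

    def test_component_means_within_three_se(self):
        mols = simulate_ogm_molecules((500, 1000), n=400, noise_sd=50.0,
                                      seed=4)
        half = len(mols.distances) // 2
        se = 3 * 50 / np.sqrt(200)
        assert abs(mols.distances[:half].mean() - 9358) <= se
        assert abs(mols.distances[half:].mean() - 11858) <= se

    def test_determinism_and_preconditions(self):
        a = simulate_ogm_molecules((0, 900), n=50, noise_sd=30, seed=7)
        b = simulate_ogm_molecules((0, 900), n=50, noise_sd=30, seed=7)
        assert np.array_equal(a.distances, b.distances)
        with pytest.raises(ValueError):
            simulate_ogm_molecules((0, 900), n=1)
        with pytest.raises(ValueError):
            simulate_ogm_molecules((-1, 900), n=10)


class TestHaplotypeSimulator:
    positions = np.arange(1000, 101001, 1000)

    def test_carriers_identical_inside_planted_interval(self):
        hap = simulate_haplotypes(10, self.positions, range(4),
                                  (30000, 60000), seed=0)
        inside = (hap.positions >= 30000) & (hap.positions <= 60000)
        carriers = hap.alleles[sorted(hap.carrier_rows)]
        assert (carriers[:, inside] == carriers[0, inside]).all()

    def test_no_spurious_sharing_among_non_carriers(self):
        # each non-carrier matches the carriers across >= 20 markers with
        # probability 0.5**20 < 1e-6 per haplotype
        hap = simulate_haplotypes(14, self.positions, range(4),
                                  (30000, 60000),
                                  background_mismatch_rate=0.5, seed=1)
        inside = (hap.positions >= 30000) & (hap.positions <= 60000)
        assert inside.sum() >= 20
        carrier = hap.alleles[0, inside]
        for row in range(4, 14):
            assert not np.array_equal(hap.alleles[row, inside], carrier)

    def test_empty_carrier_set_raises(self):
        with pytest.raises(ValueError):
            simulate_haplotypes(5, self.positions, [], (30000, 60000))

    def test_determinism(self):
        a = simulate_haplotypes(8, self.positions, range(3), (20000, 50000),
                                seed=9)
        b = simulate_haplotypes(8, self.positions, range(3), (20000, 50000),
                                seed=9)
        assert np.array_equal(a.alleles, b.alleles)

    def test_tsv_roundtrip(self, tmp_path):
        hap = simulate_haplotypes(6, self.positions, range(3),
                                  (30000, 60000), seed=2)
        path = tmp_path / "haps.tsv"
        hap.to_tsv(path)
        back = type(hap).from_tsv(path, anchor=hap.anchor)
        assert np.array_equal(back.alleles, hap.alleles)
        assert back.carrier_rows == hap.carrier_rows
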