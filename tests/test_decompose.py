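import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfc1kit import (
    decompose_read,
    decompose_tract,
    extract_tract,
    locate_tract,
    make_diploid,
    reverse_complement,
    simulate_reads,
    summarize_alleles,
    waterfall_matrix,
)

from _oracles import min_decomposition_cost


class TestLocateTract:
    def test_exact_read_recovers_the_repeat_region(self, small_het_configs):
        a1, _ = small_het_configs
        read = a1.sequence()
        loc = locate_tract(read, a1.left_anchor(), a1.right_anchor())
        assert loc.spans and loc.strand == "+"
        assert extract_tract(read, loc) == a1.tract()

    def test_reverse_complemented_read_normalizes_to_plus_strand(
            self, small_het_configs):
        a1, _ = small_het_configs
        read = reverse_complement(a1.sequence())
        loc = locate_tract(read, a1.left_anchor(), a1.right_anchor())
        assert loc.spans and loc.strand == "-"
        assert extract_tract(read, loc) == a1.tract()

    def test_truncated_read_is_open_ended_and_non_spanning(
            self, small_het_configs):
        a1, _ = small_het_configs
        read = a1.sequence()[:len(a1.left_flank) + 200]   # no right flank
        loc = locate_tract(read, a1.left_anchor(), a1.right_anchor())
        assert loc.left_anchor_found and not loc.right_anchor_found
        assert not loc.spans
        assert extract_tract(read, loc) == a1.tract()[:200]

    def test_read_without_anchors_reports_not_found(self):
        loc = locate_tract("ACGT" * 50, "TTTTTTTTTTTTTTTT", "CCCCCCCCCCCCCCCC")
        assert not loc.found and loc.start == loc.end

    def test_anchors_tolerate_a_few_edits(self, small_het_configs):
        a1, _ = small_het_configs
        read = a1.sequence()
        left = a1.left_anchor()
        noisy_left = left[:5] + ("A" if left[5] != "A" else "C") + left[6:]
        loc = locate_tract(read, noisy_left, a1.right_anchor(), max_edits=3)
        assert loc.spans
        with pytest.raises(ValueError):
            locate_tract(read, "ACGTACGT", a1.right_anchor())


class TestDecomposeTract:
    def test_pure_tract_gives_one_full_purity_segment(self):
        dec = decompose_tract("AGGGC" * 50, ["AGGGC", "AAGGG"])
        assert dec.runs == (("AGGGC", 50),)
        assert dec.segments[0].purity == 1.0
        assert dec.unassigned_bases == 0

    def test_empty_tract_gives_empty_decomposition(self):
        dec = decompose_tract("", ["AAGGG"])
        assert dec.segments == [] and dec.unassigned_bases == 0

    def test_twenty_mer_example_matches_brute_force(self):
        tract = "AAGGG" * 2 + "AAAGG" * 2
        motifs = ["AAGGG", "AAAGG"]
        # AAAGG is one mismatch per unit from AAGGG, so under the default
        # switch penalty (10) the optimum stays on AAGGG (cost 2); a switch
        # only pays once the penalty drops below the per-unit distortion.
        cost10, labels10 = min_decomposition_cost(tract, motifs, 10)
        dec = decompose_tract(tract, motifs, switch_penalty=10, min_run=1)
        assert abs(dec.cost - cost10) < 0.01
        assert (cost10, labels10) == (2, ("AAGGG",))
        assert dec.runs == (("AAGGG", 4),)

        cost1, labels1 = min_decomposition_cost(tract, motifs, 1)
        dec1 = decompose_tract(tract, motifs, switch_penalty=1, min_run=1)
        assert abs(dec1.cost - cost1) < 0.01
        assert labels1 == ("AAGGG", "AAAGG")
        assert dec1.runs == (("AAGGG", 2), ("AAAGG", 2))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="AGC", min_size=1, max_size=16),
           st.sampled_from([("AAGGG", "AAAGG"), ("AGGGC", "AAGGG"),
                            ("AGAGG", "ACAGG")]),
           st.sampled_from([3, 5, 10]))
    def test_dp_cost_equals_exhaustive_enumeration(self, tract, motifs,
                                                   penalty):
        expected, _ = min_decomposition_cost(tract, list(motifs), penalty)
        dec = decompose_tract(tract, list(motifs), switch_penalty=penalty,
                              min_run=1)
        assert abs(dec.cost - expected) < 0.01

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_conservation_of_bases(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        tract = "".join(rng.choice(list("ACGT"), size=120))
        dec = decompose_tract(tract, ["AAGGG", "AAAGG", "AGGGC"])
        covered = sum(s.end - s.start for s in dec.segments)
        assert covered + dec.unassigned_bases == len(tract)

    def test_min_run_absorbs_short_interruptions(self):
        # two-copy ACAGG interruption (distance 2/unit from AAGGG): with a
        # low switch penalty the raw path segments it out, min_run merges it
        tract = "AAGGG" * 10 + "ACAGG" * 2 + "AAGGG" * 10
        raw = decompose_tract(tract, ["AAGGG", "ACAGG"], switch_penalty=1,
                              min_run=1)
        assert raw.signature == ("AAGGG", "ACAGG", "AAGGG")
        merged = decompose_tract(tract, ["AAGGG", "ACAGG"], switch_penalty=1,
                                 min_run=3)
        assert merged.runs == (("AAGGG", 22),)
        assert merged.segments[0].purity < 1.0

    def test_boundary_between_overlapping_motifs_is_exact(self):
        # AAAGG|AGAGG share a 3-base cyclic overlap; the phase-boundary
        # tie-break must keep both copy numbers exact at zero noise
        for runs in ([("AAAGG", 470), ("AGAGG", 470)],
                     [("AGAGG", 40), ("AAAGG", 40)],
                     [("AAGGG", 51), ("AAGGC", 88)]):
            tract = "".join(m * c for m, c in runs)
            dec = decompose_tract(tract, sorted({m for m, _ in runs}))
            assert dec.runs == tuple(runs)


class TestSummarizeAlleles:
    def _decompose_all(self, reads, cfg_pair, motifs):
        decs, spans = [], []
        for read in reads:
            loc, dec = decompose_read(read.sequence,
                                      cfg_pair[0].left_anchor(),
                                      cfg_pair[0].right_anchor(), motifs,
                                      read_id=read.read_id)
            decs.append(dec)
            spans.append(loc.spans)
        return decs, spans

    def test_error_free_heterozygote_recovers_both_configurations(
            self, small_het_configs):
        a1, a2 = small_het_configs
        motifs = ["AAAGG", "AAGGG"]
        reads = simulate_reads((a1, a2), coverage=5, error_rate=0.0, seed=0)
        decs, spans = self._decompose_all(reads, (a1, a2), motifs)
        c1, c2 = summarize_alleles(decs, spans)
        assert c1.configuration.runs == a1.runs   # total 100 < 110
        assert c2.configuration.runs == a2.runs
        assert c1.supporting_reads == c2.supporting_reads == 5

    def test_homozygote_reports_one_cluster_twice(self, small_het_configs):
        a1, _ = small_het_configs
        reads = simulate_reads((a1, a1), coverage=3, error_rate=0.0, seed=1)
        decs, spans = self._decompose_all(reads, (a1, a1),
                                          ["AAAGG", "AAGGG"])
        c1, c2 = summarize_alleles(decs, spans)
        assert c1.configuration.runs == c2.configuration.runs == a1.runs
        assert c1.supporting_reads == 6

    def test_non_spanning_reads_contribute_a_size_lower_bound(
            self, small_het_configs):
        a1, _ = small_het_configs
        spanning = simulate_reads((a1, a1), coverage=2, error_rate=0.0,
                                  seed=2)
        partial = simulate_reads((a1, a1), coverage=3, error_rate=0.0,
                                 truncate_frac=1.0, seed=3)
        reads = list(spanning) + list(partial)
        decs, spans = self._decompose_all(reads, (a1, a1),
                                          ["AAAGG", "AAGGG"])
        c1, c2 = summarize_alleles(decs, spans)
        assert c1.size_lower_bound is not None
        assert c1.size_lower_bound <= c1.size_estimate

    def test_zero_spanning_reads_raise_with_guidance(self, small_het_configs):
        a1, _ = small_het_configs
        reads = simulate_reads((a1, a1), coverage=2, error_rate=0.0,
                               truncate_frac=1.0, seed=4)
        decs, spans = self._decompose_all(reads, (a1, a1),
                                          ["AAAGG", "AAGGG"])
        with pytest.raises(ValueError, match="lower bound"):
            summarize_alleles(decs, spans)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_noise_round_trip_is_exact_for_random_configurations(
            self, seed):
        rng = np.random.default_rng(seed)
        motif_pool = ["AAGGG", "AAAGG", "AAGGC", "AGGGC", "AGAGG", "ACAGG"]
        for _ in range(3):
            n_runs = int(rng.integers(1, 4))
            motifs = list(rng.choice(motif_pool, size=n_runs, replace=False))
            runs = [(m, int(rng.integers(30, 81))) for m in motifs]
            a1, a2 = make_diploid(
                runs, [(motifs[0], int(rng.integers(90, 140)))], rng)
            reads = simulate_reads((a1, a2), coverage=3, error_rate=0.0,
                                   seed=int(rng.integers(2 ** 31)))
            decs, spans = [], []
            for read in reads:
                loc, dec = decompose_read(read.sequence, a1.left_anchor(),
                                          a1.right_anchor(), sorted(motifs))
                decs.append(dec)
                spans.append(loc.spans)
            got = {c.configuration.runs for c in summarize_alleles(decs, spans)}
            assert got == {a1.runs, a2.runs}

    def test_noisy_consensus_copies_within_five_percent(self):
        rng = np.random.default_rng(99)
        a1, a2 = make_diploid([("AAAGG", 200)], [("AAGGG", 230)], rng)
        reads = simulate_reads((a1, a2), coverage=10, error_rate=0.08,
                               seed=17)
        decs, spans = self._decompose_all(reads, (a1, a2),
                                          ["AAAGG", "AAGGG"])
        c1, c2 = summarize_alleles(decs, spans)
        assert abs(c1.size_estimate - 200) <= 0.05 * 200
        assert abs(c2.size_estimate - 230) <= 0.05 * 230


class TestWaterfall:
    def test_single_read_row(self):
        dec = decompose_tract("AAGGG" * 3, ["AAGGG"])
        mat, ids, codes = waterfall_matrix([dec])
        assert mat.shape == (1, 3)
        assert (mat == codes["AAGGG"]).all()

    def test_boundary_column_equals_first_segment_copies(self):
        tract = "AAAGG" * 40 + "AAGGG" * 30
        decs = [decompose_tract(tract, ["AAAGG", "AAGGG"]) for _ in range(3)]
        mat, _, codes = waterfall_matrix(decs)
        assert mat.shape == (3, 70)
        assert (mat[:, :40] == codes["AAAGG"]).all()
        assert (mat[:, 40:] == codes["AAGGG"]).all()

    def test_rows_sorted_by_tract_length_descending(self):
        short = decompose_tract("AAGGG" * 5, ["AAGGG"], read_id="short")
        long = decompose_tract("AAGGG" * 9, ["AAGGG"], read_id="long")
        mat, ids, _ = waterfall_matrix([short, long])
        assert ids == ["long", "short"]
        assert mat.shape == (2, 9)
        assert mat[1, 5:].sum() == 0

    def test_plot_smoke(self, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        from rfc1kit.decompose import plot_waterfall
        dec = decompose_tract("AAAGG" * 10 + "AAGGG" * 5,
                              ["AAAGG", "AAGGG"])
        mat, _, codes = waterfall_matrix([dec])
        ax = plot_waterfall(mat, codes)
        ax.figure.savefig(tmp_path / "waterfall.png")
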