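# Methods

This note documents the models and procedures implemented in `rfc1kit`, the
defaults they use and why, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter for reproducibility.

## The locus and its representation

The *RFC1* intron-2 short tandem repeat is represented as an ordered list of
motif runs between two flanks: `(AAAGG)610(AAGGG)390` denotes 610 copies of
AAAGG followed by 390 copies of AAGGG. Motifs are pentanucleotides by
default (the benign AAAGGG hexamer is also accepted). Because a motif read
off a sequencing read can appear in any cyclic rotation on either strand,
all analysis is performed in a canonical frame: the lexicographically
smallest rotation taken on the G-richer strand (ties broken by the overall
lexicographic minimum, preferring the forward strand). This maps all ten
equivalent strings of a motif to one name, so `GGCAG` and `CCCTG` both
report as `AGGGC`.

## Read simulation

Reads are drawn alternately from the two alleles of a diploid locus (the
two alleles share one flank pair, as at a real locus). Errors are i.i.d.
per base at a configurable total rate with a 60:20:20
substitution:insertion:deletion mix — an indel-rich long-read-like profile;
the mix is configurable because platform error profiles vary. Each read is
reverse-complemented with probability 0.5, and a configurable fraction is
truncated at a uniform point inside the tract so that it retains exactly
one flank (a non-spanning read, as often obtained over large satellite
expansions). The generator does **not** model homopolymer-specific
basecaller errors, signal-level artefacts, coverage bias along the tract,
or chimeric reads; consequently, passing tests demonstrate correctness of
the analysis logic under a well-behaved error model, not robustness to
platform-specific failure modes.

Expansion sizes in simulated genotype tables are drawn from normal
distributions truncated at 1 repeat unit, parameterized per motif (and per
phenotype group for AAAGG: 979 ± 257 units in patients versus 238 ± 142 in
controls, the observed distributions). Samples not named in a frequency
specification receive the non-expanded reference genotype (AAAAG, 9–11
units).

## Tract location

The repeat tract is located between two anchors — the inner 20 bases of
each flank — by semi-global (infix) alignment with edlib at ≤ 3 edits per
anchor, on both strands; the orientation finding more anchors (ties: fewer
edits) wins and coordinates are normalized to the + strand. A read with one
anchor yields an open-ended, non-spanning tract contributing only a size
lower bound; a read with neither yields a not-found result rather than an
exception. Anchor uniqueness is the generator's responsibility: flanks are
rejection-sampled to share no 15-mer with the tract.

## Motif decomposition

Segmentation is a Viterbi-style minimum-cost path over (position, motif,
phase) states. Each read base is assigned one motif phase; costs are 1 per
base mismatching its phase, 1 per stalled or skipped phase (read insertion/
deletion relative to the periodic motif), and `switch_penalty` (default 10)
per motif change. The defaults were chosen so that noise-free tracts are
recovered exactly and small instances match an exhaustive-enumeration
oracle; the penalty of 10 means a run of a different motif is only called
when its evidence outweighs ten mismatch-equivalents, which suppresses
spurious switching at 8% read error while real runs (tens to hundreds of
units, each unit contributing at least one mismatch against the wrong
motif) are always worth the switch.

Two numerical details matter:

* **Boundary ties.** Adjacent runs of overlapping motifs (e.g.
  `...AAAGG|AGAGG...`, which share a 3-base cyclic overlap) admit several
  zero-cost switch positions. Switch transitions therefore carry an
  infinitesimal (2^-20) preference for leaving a motif at its last phase
  and entering the next at phase 0 — the phase-complete boundary. Integer
  costs are unchanged (oracle comparisons hold to < 0.01), and copy numbers
  become exact at zero noise for all distinct-motif pairs.
* **Short segments.** Segments shorter than `min_run` (default 3 copies)
  are absorbed into an adjacent full-length segment (or marked unassigned
  when none exists), unless no segment reaches `min_run`, in which case the
  raw segmentation is kept. Copy numbers are `round(length / motif_len)`;
  per-segment purity is the fraction of bases matching the chosen periodic
  path.

Per-allele consensus partitions spanning reads by (ordered motif signature,
total copies) with single-linkage clustering at a 20% relative length
threshold, keeps the two best-supported clusters (a diploid locus is
assumed; more clusters raise a warning), reports per-segment medians
(robust to indel-driven length noise), and duplicates the single cluster of
a homozygote. Non-spanning reads whose signature prefix/suffix matches a
unique cluster contribute a size lower bound only.

## G4 propensity

Base scores follow the run rule: a G in a run of k consecutive Gs scores
min(k, 4), a C in a run of k Cs scores −min(k, 4), A/T score 0. A candidate
region must start at the first base of a G-run of length ≥ 2, end at the
last base of one, contain exactly four such runs, and be at most `window`
(default 20) bases long — the operational definition of "four G-tracts
close enough to stack" used for region refinement here. The sequence score
is the maximum mean base score over candidates, rounded half-up to two
decimals; no candidate (or a negative best mean) means no putative G4.
Scores of `(motif)n` are constant for n ≥ 4 because the best region always
fits inside four consecutive motif copies, so motifs are scored at 10
copies by convention. This rule reproduces the published scores for
(AAGGG)10 = 2.00, (AGGGC)10 = 1.83, (AAAGG)10 = 0.94, (AGAGG)10 = 1.12 and
"no putative G4" for (AAAAG)10; the published 1.82 for (AAGGC)10 is not
reproducible from any run-scoring variant admitted by the stated
parameters (the rule yields 13/17 = 0.76) and is treated as likely
erroneous — `rfc1kit` reports the computed value.

## Configuration screen and classification

The screen reduces each allele to its dominant (largest-run) motif and
counts homozygous genotypes and genotypes compound-heterozygous with AAGGG,
per group; genotypes whose alleles are all below 50 repeat units are
treated as non-expanded reference and excluded. Percentages are
count/group-size rounded to one decimal. The association test defaults to
Pearson chi-square without continuity correction (1 df, two-sided), which
reproduces the published borderline p = 0.05 for the AAGGG/AAAGG row
(10/893 vs 47/8107, χ² = 3.73, p = 0.053); Fisher's exact test (two-sided,
hypergeometric-sum definition) is available as an option.

Classification thresholds (repeat units): AAGGG, ACAGG, AGGGC, AAGGC and
AGAGG are pathogenic from 250 — the smallest pathogenic expansion observed
for the common motif; no ACAGG-specific threshold is established, so it
inherits the generic 250, with unsized alleles returned as uncertain
rather than guessed. AAAGG is benign unless above 500 units (observed
pathogenic AAAGG runs were all ≥ 600; the 500-unit bound is the default,
and stricter values can be configured). AAAAG, AAGAG and AAAGGG are benign
at any size. A mixed-run allele is pathogenic when any constituent run
meets its own motif threshold, or when its total G-rich size exceeds 500
units with an AAGGG interruption present. The genotype call is
biallelic-pathogenic iff both alleles are pathogenic, carrier when exactly
one is, and — beyond the three obvious values — `uncertain` when no allele
is pathogenic but at least one could not be resolved (e.g. unsized AAGGG
alleles), because calling such genotypes benign would be clinically
misleading. Calls are deterministic and symmetric in allele order.

## Optical-map allele sizing

Intermarker distances are modelled as a mixture of at most two Gaussians
with a **shared** variance: the measurement noise of a labelled molecule
does not depend on which allele it came from, and tying the variance keeps
the two-component fit stable at the modest molecule counts typical of one
sample. EM is initialized at the 25th/75th percentiles with the global SD
(floor 1 bp), converges when the log-likelihood improves by less than 1e-6,
and records the per-iteration log-likelihood (asserted non-decreasing in
the tests). One- and two-component fits are compared by BIC, so a
homozygous sample cleanly selects k = 1 and both alleles get the same
size. Sizes are `round((mean − reference)/motif_len)` with reference
6858 bp (the non-expanded intermarker distance) and are floored at 0; a
mean more than 3 SD below the reference triggers a warning. At n = 400
molecules and 50 bp noise, recovered sizes have a mean absolute error well
under 5 repeat units whenever the alleles are ≥ 1000 bp apart.

## Haplotype sharing

Sharing is exact identity by state at phased markers — no probabilistic IBD
model — matching how carrier haplotypes of a recent founder expansion look
in practice. The shared interval is the maximal run of consecutive markers
containing the anchor at which all carrier rows agree; boundaries are the
outermost concordant marker positions, and the anchor maps to the first
marker at or after its coordinate. Recombinant carriers are scanned outward
from the anchor, left and right independently, for their first departure
from the core haplotype. Spans are reported as computed from coordinates
(`round((end − start)/1000)` kb): the full shared region between the outer
markers spans 207 kb, while the core region's printed coordinates
(39,302,305–39,366,034) span 64 kb even though it is conventionally quoted
as 66 kb — the toolkit reports the computed value and the demo flags the
discrepancy.

## Cohort statistics

Numeric summaries are mean ± sample SD (n−1 denominator) with range,
rounded to one decimal; the n−1 convention is pinned by a regression test
because it is the one under which the reference clinical table's SDs (13.7
and 8.7) reproduce exactly. Note that the 14 ages of onset average 51.57,
which prints as 51.6 at one decimal; the conventionally quoted 51.5 is
consistent only with truncation. Size comparisons default to the two-sided
rank-sum test (normal approximation with tie correction; sizes are skewed),
with Welch's t as an option that falls back to rank-sum under degenerate
variance. At the reference group sizes (5 patients vs 8 controls) the
rank-sum p-value cannot fall below 2/C(13,5) ≈ 0.0016; simulated groups at
the observed size distributions separate at p < 0.05 in essentially every
replicate, which is the property the tests assert.

## Reproducibility and problem sizes

Every stochastic step takes an explicit seed; one global seed fans out to
per-stage seeds by stable hashing of stage names, so stages are
independently reproducible and all derived seeds stay below 2^31. The test
suite and the acceptance script run decomposition on full-length alleles
(tracts up to 6,200 bases, 20 reads at 8% error) and mixture recovery over
100 seeded simulations of 400 molecules each; oracle-equivalence checks use
tracts up to ~16–20 bases, where exhaustive enumeration over segmentations
is provably complete given the switch penalty. These sizes were chosen to
exercise every code path at full realism for the deterministic checks while
keeping stochastic batteries comfortably small.

## Known limitations

* The decomposition assumes a diploid locus and at most two read clusters;
  somatic mosaicism is out of scope.
* Copy numbers from noisy reads inherit residual indel-imbalance bias of
  the error process; medians across reads mitigate but do not remove it.
* G4 scoring is a propensity heuristic, not a thermodynamic model; RNA G4s
  and genome-wide scanning are out of scope.
* Haplotype sharing requires phased input and detects identity by state
  only; no recombination-rate estimation or allele-age dating is performed.
* The screen's dominant-motif reduction discards within-allele composition;
  composition-aware screening would require genotype tables that preserve
  run structure (the table format does, but published screen-style counts
  do not).
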