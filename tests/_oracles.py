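"""Independent brute-force oracles used by the test suite.

These re-derive expected values by exhaustive enumeration or direct
recursion, deliberately sharing no code with the package implementation.
"""
from __future__ import annotations

import itertools
from functools import lru_cache

from scipy.stats import hypergeom

# ---------------------------------------------------------------------------
# motif canonicalization

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def canonical_oracle(motif: str) -> tuple[str, str]:
    """(canonical, strand) by explicit enumeration of all 10 candidates."""
    fwd = [motif[i:] + motif[:i] for i in range(len(motif))]
    rev = [rc(motif)[i:] + rc(motif)[:i] for i in range(len(motif))]
    g_f, g_r = motif.count("G"), rc(motif).count("G")
    if g_f > g_r:
        return min(fwd), "+"
    if g_r > g_f:
        return min(rev), "-"
    best = min(fwd + rev)
    return best, "+" if best in fwd else "-"


# ---------------------------------------------------------------------------
# G4 scoring

def g4_base_scores(seq: str) -> list[int]:
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        v = 0
        if seq[i] == "G":
            v = min(j - i, 4)
        elif seq[i] == "C":
            v = -min(j - i, 4)
        out.extend([v] * (j - i))
        i = j
    return out


def _g_run_spans(seq: str):
    spans = []
    i = 0
    while i < len(seq):
        if seq[i] == "G":
            j = i
            while j < len(seq) and seq[j] == "G":
                j += 1
            if j - i >= 2:
                spans.append((i, j))
            i = j
        else:
            i += 1
    return spans


def g4_score_oracle(seq: str, window: int = 20) -> float | None:
    """Max mean base score over every substring satisfying the candidate
    predicate, checked by sliding over all (start, end) pairs."""
    scores = g4_base_scores(seq)
    spans = _g_run_spans(seq)
    best = None
    for start in range(len(seq)):
        for end in range(start + 1, min(len(seq), start + window) + 1):
            inside = [s for s in spans if s[0] >= start and s[1] <= end]
            if len(inside) != 4:
                continue
            if not any(s[0] == start for s in inside):
                continue
            if not any(s[1] == end for s in inside):
                continue
            mean = sum(scores[start:end]) / (end - start)
            if best is None or mean > best:
                best = mean
    if best is None or best < 0:
        return None
    return best


# ---------------------------------------------------------------------------
# decomposition cost

def segment_cost(seg: str, motif: str) -> int:
    """Minimum cost of explaining one segment with one periodic motif
    (mismatch 1, stalled/skipped phase 1, free start/end phase)."""
    L = len(motif)

    @lru_cache(maxsize=None)
    def f(i: int, p: int) -> int:
        e = 0 if seg[i] == motif[p] else 1
        if i == len(seg) - 1:
            return e
        return e + min(f(i + 1, (p + 1) % L),
                       1 + f(i + 1, p),
                       1 + f(i + 1, (p + 2) % L))

    if not seg:
        return 0
    return min(f(0, p) for p in range(L))


def min_decomposition_cost(tract: str, motifs: list[str],
                           switch_penalty: int = 10) -> tuple[int, tuple]:
    """Exhaustive minimum over all segmentations and motif labelings.

    Enumerating s segments costs at least switch_penalty*(s-1), and the best
    single-segment labelling is an upper bound on the optimum, so the bound
    s <= ub1//penalty + 1 provably contains the optimum.
    """
    n = len(tract)
    if n == 0:
        return 0, ()
    ub1 = min(segment_cost(tract, m) for m in motifs)
    max_segments = ub1 // switch_penalty + 1
    best = None
    for s in range(1, max_segments + 1):
        for bounds in itertools.combinations(range(1, n), s - 1):
            cuts = (0, *bounds, n)
            segs = [tract[cuts[i]:cuts[i + 1]] for i in range(s)]
            for labels in itertools.product(motifs, repeat=s):
                if any(labels[i] == labels[i + 1] for i in range(s - 1)):
                    continue
                cost = switch_penalty * (s - 1) + sum(
                    segment_cost(seg, m) for seg, m in zip(segs, labels))
                key = (cost, labels, cuts)
                if best is None or cost < best[0]:
                    best = key
    return best[0], best[1]


# ---------------------------------------------------------------------------
# Fisher exact

def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities <= the
    observed table's, enumerated over all tables with fixed margins."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = hypergeom.pmf(k, n, col1, row1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# shared haplotype interval

def shared_interval_oracle(alleles, positions, carriers, anchor_index):
    """Widest anchor-containing interval of all-concordant columns, by
    scanning every (i, j) pair."""
    sub = alleles[sorted(carriers)]
    conc = [all(sub[r][j] == sub[0][j] for r in range(len(sub)))
            for j in range(sub.shape[1])]
    best = None
    for i in range(anchor_index + 1):
        for j in range(anchor_index, sub.shape[1]):
            if i <= anchor_index <= j and all(conc[i:j + 1]):
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
    return best
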