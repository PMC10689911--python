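"""G-quadruplex propensity scoring of repeat motifs and sequences.

Run-based base scoring: every G in a maximal run of k consecutive Gs scores
``min(k, 4)``, every C in a run of k Cs scores ``-min(k, 4)``, and A/T score
0.  A putative quadruplex needs four G-tracts close together, so candidate
regions are the substrings of length at most ``window`` (default 20) that
start at the first base of a G-run of length >= 2, end at the last base of a
G-run of length >= 2 and contain exactly four such runs.  The sequence score
is the maximum arithmetic mean of the base scores over candidate regions,
rounded half-up to two decimals; a sequence with no qualifying region (or
none with a non-negative mean) forms no putative G4 and scores ``None``.

Scores saturate once four G-runs fit inside the window, so scoring a motif
expanded to 10 copies is representative of arbitrarily long expansions.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .motifs import DNA_ALPHABET

DEFAULT_WINDOW = 20
DEFAULT_THRESHOLD = 1.5


@dataclass
class G4Result:
    sequence: str
    base_scores: list[int]
    best_region: tuple[int, int, float] | None   # (start, end, mean), 0-based half-open
    score: float | None
    window: int = DEFAULT_WINDOW
    threshold: float = DEFAULT_THRESHOLD

    @property
    def forms_g4(self) -> bool:
        return self.score is not None and self.score >= self.threshold


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


def base_scores(sequence: str) -> list[int]:
    """Per-base G/C run scores in [-4, 4]."""
    seq = sequence.upper()
    if not set(seq) <= DNA_ALPHABET:
        raise ValueError("sequence contains non-ACGT characters")
    out = [0] * len(seq)
    i = 0
    while i < len(seq):
        b = seq[i]
        if b in "GC":
            j = i
            while j < len(seq) and seq[j] == b:
                j += 1
            val = min(j - i, 4) * (1 if b == "G" else -1)
            for t in range(i, j):
                out[t] = val
            i = j
        else:
            i += 1
    return out


def _g_runs(seq: str, min_len: int = 2) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "G":
            j = i
            while j < len(seq) and seq[j] == "G":
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def g4_score(sequence: str, window: int = DEFAULT_WINDOW,
             threshold: float = DEFAULT_THRESHOLD) -> G4Result:
    """Score a sequence's propensity to form a G-quadruplex."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    scores = base_scores(seq)
    runs = _g_runs(seq)
    best: tuple[int, int, float] | None = None
    for a in range(len(runs) - 3):
        start = runs[a][0]
        end = runs[a + 3][1]
        if end - start > window:
            continue
        mean = sum(scores[start:end]) / (end - start)
        if best is None or mean > best[2]:
            best = (start, end, mean)
    if best is None or best[2] < 0:
        return G4Result(seq, scores, None, None, window, threshold)
    return G4Result(seq, scores, best, _round2(best[2]), window, threshold)


def score_motif(motif: str, copies: int = 10, window: int = DEFAULT_WINDOW,
                threshold: float = DEFAULT_THRESHOLD) -> G4Result:
    """Score a repeat motif expanded to ``copies`` repeats."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    return g4_score(motif.upper() * copies, window=window, threshold=threshold)


def score_motifs(motifs: Sequence[str], copies: int = 10,
                 window: int = DEFAULT_WINDOW,
                 threshold: float = DEFAULT_THRESHOLD) -> dict[str, G4Result]:
    return {m: score_motif(m, copies, window, threshold) for m in motifs}
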