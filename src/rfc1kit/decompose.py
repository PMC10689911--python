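"""Long-read repeat-tract location and motif decomposition.

Given reads over an expanded repeat locus, this module (i) locates the repeat
tract between two unique flank anchors with semi-global alignment, (ii)
segments the tract into ordered motif runs by a Viterbi-style minimum-cost
path over (position, motif, phase) states, (iii) combines per-read
decompositions into at most two per-allele consensus configurations, and
(iv) renders the classic waterfall matrix (one row per read, one column per
repeat unit, cells coded by motif).

Cost model of the segmentation: each read base is assigned one motif phase;
a base mismatching its phase costs 1, a stalled or skipped phase (read
insertion/deletion relative to the periodic motif) costs 1, and changing
motif costs ``switch_penalty`` (default 10).  Switches additionally carry an
infinitesimal (2^-20) preference for occurring at motif-phase boundaries,
which resolves zero-cost boundary ambiguity between overlapping motifs
(e.g. ``...AAAGG|AGAGG...``) without affecting the integer cost; copy
numbers are then exact on noise-free input.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Sequence

import edlib
import numpy as np

from .motifs import RepeatConfiguration, reverse_complement

_EPS = 2.0 ** -20


# ---------------------------------------------------------------------------
# tract location

@dataclass(frozen=True)
class TractLocation:
    """Repeat-tract interval within a read, on the + strand after
    orientation normalization (0-based, half-open)."""

    read_id: str | None
    start: int
    end: int
    left_anchor_found: bool
    right_anchor_found: bool
    strand: str = "+"

    @property
    def spans(self) -> bool:
        return self.left_anchor_found and self.right_anchor_found

    @property
    def found(self) -> bool:
        return self.left_anchor_found or self.right_anchor_found


def _best_hit(query: str, target: str, max_edits: int):
    res = edlib.align(query, target, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return None
    s, e = res["locations"][0]
    return s, e + 1, res["editDistance"]


def locate_tract(read: str, left_anchor: str, right_anchor: str,
                 max_edits: int = 3, read_id: str | None = None
                 ) -> TractLocation:
    """Locate the repeat tract between flank anchors in a read.

    Both anchors (>= 15 bases recommended) are searched semi-globally on both
    strands; the orientation with more anchors found (ties broken by fewer
    edits) wins, and coordinates are reported on the + strand.  A read
    missing one anchor yields an open-ended, non-spanning tract; a read
    missing both yields a not-found result rather than an exception.
    """
    if min(len(left_anchor), len(right_anchor)) < 15:
        raise ValueError("anchors must be at least 15 bases")
    read = read.upper()
    candidates = []
    for strand, seq in (("+", read), ("-", reverse_complement(read))):
        lh = _best_hit(left_anchor.upper(), seq, max_edits)
        rh = _best_hit(right_anchor.upper(), seq, max_edits)
        n_found = (lh is not None) + (rh is not None)
        edits = (lh[2] if lh else 0) + (rh[2] if rh else 0)
        candidates.append((-n_found, edits, strand, lh, rh))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    _, _, strand, lh, rh = candidates[0]

    if lh is None and rh is None:
        return TractLocation(read_id, 0, 0, False, False, "+")
    start = lh[1] if lh else 0
    end = rh[0] if rh else len(read)
    if end < start:          # anchors out of order: degenerate empty tract
        end = start
    return TractLocation(read_id, start, end,
                         lh is not None, rh is not None, strand)


def extract_tract(read: str, location: TractLocation) -> str:
    """Return the tract substring on the + strand."""
    seq = read.upper()
    if location.strand == "-":
        seq = reverse_complement(seq)
    return seq[location.start:location.end]


# ---------------------------------------------------------------------------
# motif segmentation

@dataclass(frozen=True)
class Segment:
    motif: str
    copies: int
    start: int
    end: int
    purity: float


@dataclass
class Decomposition:
    """Segmentation of one read's repeat tract into ordered motif runs."""

    read_id: str | None
    segments: list[Segment]
    unassigned_bases: int
    tract_length: int
    cost: float = 0.0

    @property
    def signature(self) -> tuple[str, ...]:
        return tuple(s.motif for s in self.segments)

    @property
    def total_copies(self) -> int:
        return sum(s.copies for s in self.segments)

    @property
    def runs(self) -> tuple[tuple[str, int], ...]:
        return tuple((s.motif, s.copies) for s in self.segments)

    def notation(self) -> str:
        from .motifs import format_runs
        return format_runs(self.runs)


def _periodic_matches(seq: str, motif: str) -> int:
    L = len(motif)
    best = 0
    for ph in range(L):
        best = max(best, sum(seq[i] == motif[(i + ph) % L]
                             for i in range(len(seq))))
    return best


def decompose_tract(tract: str, motif_set: Sequence[str],
                    switch_penalty: float = 10.0, min_run: int = 3,
                    read_id: str | None = None) -> Decomposition:
    """Segment a repeat tract into ordered motif runs by minimum-cost path.

    Every tract position is labelled with one motif (phase tracked per
    state); the optimal labelling is found by dynamic programming and merged
    into segments.  Segments shorter than ``min_run`` copies are absorbed
    into an adjacent full-length segment, or marked unassigned when no such
    neighbour exists (unless no segment reaches ``min_run``, in which case
    the raw segmentation is kept).  ``copies = round(length / motif_len)``.
    """
    if not motif_set:
        raise ValueError("motif_set must not be empty")
    motifs = [m.upper() for m in motif_set]
    tract = tract.upper()
    n = len(tract)
    if n == 0:
        return Decomposition(read_id, [], 0, 0, 0.0)
    if switch_penalty <= 0:
        raise ValueError("switch_penalty must be > 0")

    # state layout: contiguous blocks of phases per motif
    state_motif: list[int] = []
    state_phase: list[int] = []
    match_base: list[str] = []
    adv_from: list[int] = []
    skip_from: list[int] = []
    offset = 0
    blocks: list[slice] = []
    for mi, m in enumerate(motifs):
        L = len(m)
        blocks.append(slice(offset, offset + L))
        for p in range(L):
            state_motif.append(mi)
            state_phase.append(p)
            match_base.append(m[p])
            adv_from.append(offset + (p - 1) % L)
            skip_from.append(offset + (p - 2) % L)
        offset += L
    S = offset
    state_motif_a = np.array(state_motif)
    adv_from_a = np.array(adv_from)
    skip_from_a = np.array(skip_from)
    match_codes = np.frombuffer("".join(match_base).encode(), dtype=np.uint8)
    tract_codes = np.frombuffer(tract.encode(), dtype=np.uint8)
    land_pref = _EPS * (np.array(state_phase) != 0)
    leave_pref = np.array([_EPS * (state_phase[s] != len(motifs[state_motif[s]]) - 1)
                           for s in range(S)])

    emit = (tract_codes[:, None] != match_codes[None, :]).astype(np.float64)

    cost = emit[0].copy()
    back = np.full((n, S), -1, dtype=np.int32)
    for i in range(1, n):
        # within-motif moves: advance (0), stall (+1), skip (+1)
        adv = cost[adv_from_a]
        stall = cost + 1.0
        skip = cost[skip_from_a] + 1.0
        within = adv
        within_src = adv_from_a.copy()
        better = stall < within
        within = np.where(better, stall, within)
        within_src = np.where(better, np.arange(S), within_src)
        better = skip < within
        within = np.where(better, skip, within)
        within_src = np.where(better, skip_from_a, within_src)

        # switch moves: from the best state of any *other* motif
        leave = cost + leave_pref
        block_best = np.empty(len(motifs))
        block_arg = np.empty(len(motifs), dtype=np.int64)
        for mi, bl in enumerate(blocks):
            j = int(np.argmin(leave[bl]))
            block_best[mi] = leave[bl][j]
            block_arg[mi] = bl.start + j
        order = np.argsort(block_best, kind="stable")
        best_m, second_m = order[0], (order[1] if len(order) > 1 else order[0])
        sw_val = np.where(state_motif_a == best_m,
                          block_best[second_m], block_best[best_m])
        sw_src = np.where(state_motif_a == best_m,
                          block_arg[second_m], block_arg[best_m])
        if len(motifs) == 1:
            sw_val = np.full(S, np.inf)
        sw_val = sw_val + switch_penalty + land_pref

        use_switch = sw_val < within
        new = np.where(use_switch, sw_val, within) + emit[i]
        back[i] = np.where(use_switch, sw_src, within_src)
        cost = new

    # backtrack
    s = int(np.argmin(cost))
    total_cost = float(cost[s])
    labels = np.empty(n, dtype=np.int64)
    matched = np.empty(n, dtype=bool)
    for i in range(n - 1, -1, -1):
        labels[i] = state_motif[s]
        matched[i] = emit[i, s] == 0.0
        s = int(back[i, s]) if i > 0 else s

    segments = _labels_to_segments(labels, matched, motifs)
    segments, unassigned = _apply_min_run(segments, tract, min_run)
    return Decomposition(read_id, segments, unassigned, n, total_cost)


def _labels_to_segments(labels: np.ndarray, matched: np.ndarray,
                        motifs: list[str]) -> list[Segment]:
    segments = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            motif = motifs[labels[start]]
            length = i - start
            segments.append(Segment(
                motif=motif,
                copies=int(round(length / len(motif))),
                start=start, end=i,
                purity=float(matched[start:i].mean()),
            ))
            start = i
    return segments


def _apply_min_run(segments: list[Segment], tract: str, min_run: int
                   ) -> tuple[list[Segment], int]:
    if min_run <= 1 or len(segments) <= 1:
        return segments, 0
    if not any(s.copies >= min_run for s in segments):
        return segments, 0
    segs = list(segments)
    unassigned = 0
    while True:
        short = [k for k, s in enumerate(segs) if s.copies < min_run]
        if not short:
            break
        k = min(short, key=lambda k: segs[k].end - segs[k].start)
        s = segs[k]
        neighbours = [j for j in (k - 1, k + 1)
                      if 0 <= j < len(segs)
                      and segs[j].copies >= min_run
                      and (segs[j].end == s.start or segs[j].start == s.end)]
        if neighbours:
            j = max(neighbours, key=lambda j: segs[j].end - segs[j].start)
            nb = segs[j]
            lo, hi = min(nb.start, s.start), max(nb.end, s.end)
            nb_len = nb.end - nb.start
            extra = _periodic_matches(tract[s.start:s.end], nb.motif)
            purity = (nb.purity * nb_len + extra) / (hi - lo)
            segs[j] = Segment(nb.motif, int(round((hi - lo) / len(nb.motif))),
                              lo, hi, purity)
            del segs[k]
        else:
            unassigned += s.end - s.start
            del segs[k]
    # adjacent same-motif segments may now touch: merge them
    merged: list[Segment] = []
    for s in segs:
        if merged and merged[-1].motif == s.motif and merged[-1].end == s.start:
            prev = merged.pop()
            lo, hi = prev.start, s.end
            purity = (prev.purity * (prev.end - prev.start)
                      + s.purity * (s.end - s.start)) / (hi - lo)
            merged.append(Segment(s.motif, int(round((hi - lo) / len(s.motif))),
                                  lo, hi, purity))
        else:
            merged.append(s)
    return merged, unassigned


def decompose_read(read: str, left_anchor: str, right_anchor: str,
                   motif_set: Sequence[str], max_edits: int = 3,
                   switch_penalty: float = 10.0, min_run: int = 3,
                   read_id: str | None = None
                   ) -> tuple[TractLocation, Decomposition]:
    """Locate and decompose the repeat tract of one read."""
    loc = locate_tract(read, left_anchor, right_anchor, max_edits, read_id)
    tract = extract_tract(read, loc) if loc.found else ""
    return loc, decompose_tract(tract, motif_set, switch_penalty, min_run,
                                read_id=read_id)


# ---------------------------------------------------------------------------
# per-allele consensus

@dataclass
class AlleleConsensus:
    allele_id: int
    configuration: RepeatConfiguration
    supporting_reads: int
    size_estimate: int
    size_lower_bound: int | None = None

    def notation(self) -> str:
        return self.configuration.notation()


def summarize_alleles(decompositions: Sequence[Decomposition],
                      spans_flags: Sequence[bool],
                      rel_length_threshold: float = 0.2
                      ) -> tuple[AlleleConsensus, AlleleConsensus]:
    """Combine per-read decompositions into two per-allele consensuses.

    Spanning reads are partitioned into at most two clusters by (ordered
    motif signature, total copies) with single-linkage at a relative length
    threshold; cluster consensus copies are per-segment medians.  A
    homozygous input yields one cluster reported twice.  Non-spanning reads
    whose signature matches a unique cluster's prefix or suffix contribute
    only a size lower bound.
    """
    if len(decompositions) != len(spans_flags):
        raise ValueError("decompositions and spans_flags must align")
    spanning = [d for d, sp in zip(decompositions, spans_flags)
                if sp and d.segments]
    partial = [d for d, sp in zip(decompositions, spans_flags)
               if not sp and d.segments]
    if not spanning:
        raise ValueError(
            "no spanning reads: only size lower bounds are available; "
            "inspect partial decompositions directly")

    # group by signature, then single-linkage on total copies
    clusters: list[list[Decomposition]] = []
    by_sig: dict[tuple[str, ...], list[Decomposition]] = {}
    for d in spanning:
        by_sig.setdefault(d.signature, []).append(d)
    for sig in sorted(by_sig):
        group = sorted(by_sig[sig], key=lambda d: d.total_copies)
        current = [group[0]]
        for d in group[1:]:
            if (d.total_copies - current[-1].total_copies
                    <= rel_length_threshold * d.total_copies):
                current.append(d)
            else:
                clusters.append(current)
                current = [d]
        clusters.append(current)

    if len(clusters) > 2:
        warnings.warn(f"{len(clusters)} read clusters at a diploid locus; "
                      "keeping the two best-supported", stacklevel=2)
        clusters.sort(key=lambda c: (-len(c),
                                     -int(median(d.total_copies for d in c))))
        clusters = clusters[:2]
    if len(clusters) == 1:
        clusters = [clusters[0], clusters[0]]

    consensuses = []
    for cl in clusters:
        sig = cl[0].signature
        runs = tuple(
            (motif, int(round(median(d.segments[k].copies for d in cl))))
            for k, motif in enumerate(sig))
        consensuses.append(AlleleConsensus(
            allele_id=0,
            configuration=RepeatConfiguration(runs),
            supporting_reads=len(cl),
            size_estimate=int(round(median(d.total_copies for d in cl))),
        ))
    consensuses.sort(key=lambda c: (c.size_estimate, c.configuration.motifs))
    for i, c in enumerate(consensuses):
        c.allele_id = i + 1

    for d in partial:
        sig = d.signature
        hits = [c for c in consensuses
                if c.configuration.motifs[:len(sig)] == sig
                or c.configuration.motifs[-len(sig):] == sig]
        if hits and len({c.notation() for c in hits}) == 1:
            c = hits[0]
            c.size_lower_bound = max(d.total_copies, c.size_lower_bound or 0)
    return consensuses[0], consensuses[1]


# ---------------------------------------------------------------------------
# waterfall matrix

def waterfall_matrix(decompositions: Sequence[Decomposition],
                     motif_order: Sequence[str] | None = None
                     ) -> tuple[np.ndarray, list[str | None], dict[str, int]]:
    """Render decompositions as a waterfall matrix.

    One row per read, one column per repeat-unit index; cells hold 1-based
    motif codes (0 = unassigned padding).  Rows are sorted by tract length
    descending (ties by read id) — the familiar waterfall ordering.
    """
    if not decompositions:
        raise ValueError("no decompositions")
    motifs = list(motif_order) if motif_order else sorted(
        {s.motif for d in decompositions for s in d.segments})
    codes = {m: i + 1 for i, m in enumerate(motifs)}
    rows = []
    order = sorted(decompositions,
                   key=lambda d: (-d.tract_length, str(d.read_id)))
    for d in order:
        row: list[int] = []
        cursor = 0
        for s in d.segments:
            gap = s.start - cursor
            if gap > 0:
                row.extend([0] * int(round(gap / 5)))
            row.extend([codes[s.motif]] * s.copies)
            cursor = s.end
        rows.append(row)
    width = max((len(r) for r in rows), default=0)
    mat = np.zeros((len(rows), width), dtype=np.int64)
    for i, r in enumerate(rows):
        mat[i, :len(r)] = r
    return mat, [d.read_id for d in order], codes


def plot_waterfall(matrix: np.ndarray, codes: dict[str, int], ax=None):
    """Plot a waterfall matrix (one coloured cell per repeat unit)."""
    import matplotlib
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _, ax = plt.subplots(figsize=(8, max(2, 0.2 * matrix.shape[0])))
    palette = ["#ffffff", "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728",
               "#9467bd", "#8c564b", "#e377c2", "#7f7f7f"]
    cmap = ListedColormap(palette[:len(codes) + 1])
    ax.imshow(matrix, aspect="auto", interpolation="nearest",
              cmap=cmap, vmin=0, vmax=len(codes))
    ax.set_xlabel("repeat unit")
    ax.set_ylabel("read")
    handles = [matplotlib.patches.Patch(color=palette[c], label=m)
               for m, c in codes.items()]
    ax.legend(handles=handles, loc="upper right", fontsize="small")
    return ax
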