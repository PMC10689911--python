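"""Shared-haplotype interval detection around a repeat locus.

Carrier chromosomes descending from a common ancestral expansion are
identical by state over a marker interval around the locus.  Sharing is
defined as exact identity at phased markers: the shared interval is the
maximal run of consecutive markers containing the anchor at which all
carrier rows agree.  A recombinant carrier — one that departs from the core
haplotype on one side — is reported with its breakpoint marker per side.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .simulate import HaplotypeMatrix


@dataclass(frozen=True)
class SharedInterval:
    start_pos: int
    end_pos: int
    start_index: int
    end_index: int            # inclusive marker indices
    n_markers: int

    @property
    def empty(self) -> bool:
        return self.n_markers == 0

    @property
    def span_kb(self) -> int:
        return span_kb(self.start_pos, self.end_pos)


def _anchor_index(positions: np.ndarray, anchor: int) -> int:
    i = int(np.searchsorted(positions, anchor, side="left"))
    return min(i, len(positions) - 1)


def shared_interval(matrix: HaplotypeMatrix,
                    carriers: Iterable[int] | None = None) -> SharedInterval:
    """Maximal anchor-containing run of markers where all carriers agree.

    Boundaries are the outermost concordant marker positions.  Carriers
    discordant at the anchor marker itself yield an empty interval.
    """
    rows = sorted(carriers) if carriers is not None else sorted(matrix.carrier_rows)
    if len(rows) < 2:
        raise ValueError("need at least 2 carrier rows")
    sub = matrix.alleles[rows]
    concordant = (sub == sub[0]).all(axis=0)
    ia = _anchor_index(matrix.positions, matrix.anchor)
    if not concordant[ia]:
        return SharedInterval(matrix.anchor, matrix.anchor, ia, ia, 0)
    lo = ia
    while lo > 0 and concordant[lo - 1]:
        lo -= 1
    hi = ia
    while hi < len(concordant) - 1 and concordant[hi + 1]:
        hi += 1
    return SharedInterval(int(matrix.positions[lo]), int(matrix.positions[hi]),
                          lo, hi, hi - lo + 1)


@dataclass(frozen=True)
class RecombinationBreakpoints:
    """First departure from the core haplotype per side of the anchor
    (marker bp positions; ``None`` = concordant throughout on that side)."""
    left: int | None
    right: int | None


def detect_recombinant(matrix: HaplotypeMatrix,
                       core_carriers: Iterable[int],
                       candidates: Iterable[int] | None = None
                       ) -> Mapping[int, RecombinationBreakpoints]:
    """Breakpoints of carriers excluded from the core consensus.

    The core haplotype is the (identical) allele sequence of
    ``core_carriers`` over their shared interval; each candidate carrier is
    scanned outward from the anchor, left and right independently, for the
    first marker where it departs from the core haplotype.
    """
    core_rows = sorted(core_carriers)
    core = shared_interval(matrix, core_rows)
    if core.empty:
        raise ValueError("core carriers are discordant at the anchor")
    if candidates is None:
        candidates = sorted(set(matrix.carrier_rows) - set(core_rows))
    consensus = matrix.alleles[core_rows[0]]
    ia = _anchor_index(matrix.positions, matrix.anchor)

    out: dict[int, RecombinationBreakpoints] = {}
    for row in candidates:
        hap = matrix.alleles[row]
        left = right = None
        for j in range(ia, core.start_index - 1, -1):
            if hap[j] != consensus[j]:
                left = int(matrix.positions[j])
                break
        for j in range(ia, core.end_index + 1):
            if hap[j] != consensus[j]:
                right = int(matrix.positions[j])
                break
        out[int(row)] = RecombinationBreakpoints(left, right)
    return out


def span_kb(start_pos: int, end_pos: int) -> int:
    """Interval span in kb, rounded to the nearest integer."""
    if end_pos < start_pos:
        raise ValueError("end must be >= start")
    return int(round((end_pos - start_pos) / 1000))
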