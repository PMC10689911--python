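"""Repeat-motif primitives.

The RFC1 intron-2 locus harbours a pentanucleotide short tandem repeat whose
alleles are described as ordered runs of motifs, written in the field's usual
notation ``(AAAGG)610(AAGGG)390``.  This module holds the shared vocabulary:
reverse complement, canonical motif frames, the notation parser/formatter and
the :class:`RepeatConfiguration` container used throughout the package.

A motif read off a sequencing read can appear in any of its cyclic rotations
and on either strand; ``canonicalize_motif`` maps all ten equivalent strings
to one canonical frame (the lexicographically smallest rotation taken on the
G-richer strand) so that, e.g., ``GGCAG`` and ``CCCTG`` both report as
``AGGGC``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Motif frames used at the RFC1 locus (pentanucleotides plus the benign
#: AAAGGG hexanucleotide), in canonical form.
RFC1_MOTIFS = (
    "AAGGG", "AAAGG", "AAGGC", "AGGGC", "AGAGG",
    "ACAGG", "AAAAG", "AAGAG", "AAAGGG",
)

_NOTATION_RE = re.compile(r"\(([ACGTacgt]+)\)(\d+|n)")


class ConfigurationError(ValueError):
    """Raised when a repeat configuration violates its invariants."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_motif(motif: str, lengths: Sequence[int] = (5, 6)) -> str:
    m = motif.upper()
    if len(m) not in lengths:
        raise ConfigurationError(
            f"motif {motif!r} has length {len(m)}, expected one of {tuple(lengths)}"
        )
    if not set(m) <= DNA_ALPHABET:
        raise ConfigurationError(f"motif {motif!r} contains non-ACGT characters")
    return m


def canonicalize_motif(motif: str) -> tuple[str, int, str]:
    """Map a motif to its canonical frame.

    Returns ``(canonical, rotation_offset, strand)`` where ``canonical`` is
    the lexicographically smallest rotation of the motif taken on the
    G-richer strand, ``rotation_offset`` is the rotation applied on that
    strand, and ``strand`` is ``'+'`` if the input strand was kept or ``'-'``
    if its reverse complement was.  Ties in G content are broken by the
    overall lexicographic minimum, preferring the ``'+'`` strand.

    Idempotent: ``canonicalize_motif(canonical)[0] == canonical``.
    """
    m = _validate_motif(motif)
    rc = reverse_complement(m)

    def best_rotation(s: str) -> tuple[str, int]:
        return min((s[i:] + s[:i], i) for i in range(len(s)))

    g_fwd, g_rev = m.count("G"), rc.count("G")
    if g_fwd > g_rev:
        candidates = [(best_rotation(m), "+")]
    elif g_rev > g_fwd:
        candidates = [(best_rotation(rc), "-")]
    else:
        candidates = [(best_rotation(m), "+"), (best_rotation(rc), "-")]
    (canonical, offset), strand = min(candidates)
    return canonical, offset, strand


@dataclass(frozen=True)
class RepeatConfiguration:
    """One repeat allele: ordered motif runs between unique flanks.

    ``runs`` is an ordered sequence of ``(motif, copies)`` pairs, e.g.
    ``[("AAAGG", 610), ("AAGGG", 390)]``.  Flanks may be empty; when the
    configuration is produced by the synthetic-data generator they are
    guaranteed to share no 15-mer with the repeat tract, so their inner ends
    serve as unique anchors for tract location.
    """

    runs: tuple[tuple[str, int], ...]
    left_flank: str = ""
    right_flank: str = ""

    def __post_init__(self):
        runs = tuple((_validate_motif(m), int(c)) for m, c in self.runs)
        if not runs:
            raise ConfigurationError("configuration needs at least one motif run")
        for m, c in runs:
            if c < 1:
                raise ConfigurationError(f"run ({m}, {c}): copies must be >= 1")
        for name in ("left_flank", "right_flank"):
            f = getattr(self, name).upper()
            if not set(f) <= DNA_ALPHABET:
                raise ConfigurationError(f"{name} contains non-ACGT characters")
            object.__setattr__(self, name, f)
        object.__setattr__(self, "runs", runs)

    @classmethod
    def from_notation(cls, text: str, left_flank: str = "",
                      right_flank: str = "") -> "RepeatConfiguration":
        runs = parse_runs(text, allow_unknown=False)
        return cls(tuple(runs), left_flank, right_flank)

    def notation(self) -> str:
        return format_runs(self.runs)

    def tract(self) -> str:
        return "".join(m * c for m, c in self.runs)

    def sequence(self) -> str:
        return self.left_flank + self.tract() + self.right_flank

    @property
    def total_copies(self) -> int:
        return sum(c for _, c in self.runs)

    @property
    def motifs(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.runs)

    def left_anchor(self, k: int = 20) -> str:
        return self.left_flank[-k:]

    def right_anchor(self, k: int = 20) -> str:
        return self.right_flank[:k]


def parse_runs(text: str, allow_unknown: bool = True) -> list[tuple[str, int | None]]:
    """Parse configuration notation ``(MOTIF)count(MOTIF)count``.

    A bare motif (``AAGGG``) parses as a single run with unknown copies.
    ``(AAGGG)n`` denotes a run of unknown size (``copies=None``) when
    ``allow_unknown`` is true.
    """
    text = text.strip()
    if not text:
        raise ConfigurationError("empty configuration string")
    if "(" not in text:
        _validate_motif(text)
        if not allow_unknown:
            raise ConfigurationError(f"{text!r} has no copy number")
        return [(text.upper(), None)]
    runs: list[tuple[str, int | None]] = []
    pos = 0
    for match in _NOTATION_RE.finditer(text):
        if match.start() != pos:
            raise ConfigurationError(f"cannot parse configuration {text!r}")
        motif = _validate_motif(match.group(1))
        copies: int | None = None if match.group(2) == "n" else int(match.group(2))
        if copies is None and not allow_unknown:
            raise ConfigurationError(f"unknown copy number in {text!r}")
        runs.append((motif, copies))
        pos = match.end()
    if pos != len(text) or not runs:
        raise ConfigurationError(f"cannot parse configuration {text!r}")
    return runs


def format_runs(runs: Sequence[tuple[str, int | None]]) -> str:
    return "".join(f"({m}){'n' if c is None else c}" for m, c in runs)


def build_allele_sequence(config: RepeatConfiguration) -> str:
    """Expand a configuration into its full allele sequence.

    Returns ``left_flank + motif runs in order + right_flank``; the length is
    ``len(left) + len(right) + sum(len(motif) * copies)``.
    """
    return config.sequence()
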