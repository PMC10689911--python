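"""Flat key=value pipeline configuration."""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .motifs import DNA_ALPHABET

DEFAULT_MOTIFS = ("AAGGG", "AAAGG", "AAGGC", "AGGGC", "AGAGG",
                  "AAAAG", "AAGAG", "ACAGG", "AAAGGG")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    left_anchor: str | None = None
    right_anchor: str | None = None
    pathogenic_min: int = 250
    aaagg_pathogenic_min: int = 500
    ogm_reference: float = 6858.0
    motif_len: int = 5
    g4_window: int = 20
    g4_threshold: float = 1.5
    switch_penalty: float = 10.0
    min_run: int = 3

    def __post_init__(self):
        self.motifs = tuple(m.upper() for m in self.motifs)
        for m in self.motifs:
            if not set(m) <= DNA_ALPHABET or not 5 <= len(m) <= 6:
                raise ConfigError(f"invalid motif {m!r}")
        for key in ("pathogenic_min", "aaagg_pathogenic_min", "g4_window",
                    "motif_len", "min_run"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be positive")
        if self.switch_penalty <= 0 or self.g4_threshold < 0:
            raise ConfigError("invalid threshold value")


_INT_KEYS = {"seed", "pathogenic_min", "aaagg_pathogenic_min", "motif_len",
             "g4_window", "min_run"}
_FLOAT_KEYS = {"ogm_reference", "g4_threshold", "switch_penalty"}


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file.

    Unknown keys raise a :class:`ConfigError` naming them; ``#`` starts a
    comment; ``motifs`` is a comma-separated list.  The seed key is
    mandatory so that every downstream stage is reproducible.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    known = {f.name for f in fields(PipelineConfig)}
    values: dict = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in known:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r} "
                              f"(known keys: {', '.join(sorted(known))})")
        try:
            if key == "motifs":
                values[key] = tuple(v.strip().upper()
                                    for v in val.split(",") if v.strip())
            elif key in _INT_KEYS:
                values[key] = int(val)
            elif key in _FLOAT_KEYS:
                values[key] = float(val)
            else:
                values[key] = val
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key}: {val!r}") from exc
    if "seed" not in values:
        raise ConfigError(f"{path}: mandatory key 'seed' missing")
    return PipelineConfig(**values)
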