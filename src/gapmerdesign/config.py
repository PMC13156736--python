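"""Threshold and geometry configuration for the design pipeline.

All tier thresholds default to the favorable/unfavorable profile observed
across approved gapmer drugs (GC in [0.3, 0.6], MFE > -2 kcal/mol,
RNase H1 score < 0.2, essentially no close off-targets) and its mirror
image for the unfavorable tier (MFE < -5, GC in [0.2, 0.3) or (0.6, 0.75],
more than 10 transcripts at exactly 4 mismatches, RNase H1 score >= 0.5).
Every value can be overridden from a YAML key-value file or per-call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

#: Preclinical species routinely used for in vivo gapmer validation.
CANONICAL_SPECIES: tuple[str, ...] = (
    "monkey", "mouse", "rat", "rabbit", "pig", "guinea_pig",
)


@dataclass(frozen=True)
class DesignConfig:
    """Bundle of window geometry, thresholds and pipeline switches."""

    #: target-site / ASO length in nt (canonical 5-10-5 gapmer -> 20)
    window: int = 20
    #: maximum Hamming distance tracked by the off-target search
    max_mismatches: int = 4

    # favorable-tier bounds (all must hold)
    gc_favorable_min: float = 0.3   # inclusive
    gc_favorable_max: float = 0.6   # inclusive
    mfe_favorable: float = -2.0     # favorable iff mfe > this, strictly
    rnaseh1_favorable: float = 0.2  # favorable iff score < this, strictly
    offtarget_close_max: int = 0    # max allowed transcripts at mm < 4
    offtarget_mm4_max: int = 10     # max allowed transcripts at mm == 4

    # unfavorable-tier bounds (any one suffices)
    gc_unfavorable_low: tuple[float, float] = (0.2, 0.3)    # [low, high)
    gc_unfavorable_high: tuple[float, float] = (0.6, 0.75)  # (low, high]
    mfe_unfavorable: float = -5.0    # unfavorable iff mfe < this, strictly
    rnaseh1_unfavorable: float = 0.5  # unfavorable iff score >= this
    offtarget_close_unfavorable: int = 2  # unfavorable iff mm<4 count > this

    species: tuple[str, ...] = CANONICAL_SPECIES
    #: minimum identity for --require-species filtering (1.0 = perfect)
    min_identity: float = 1.0
    #: path to the RNase H1 weight table; None -> shipped placeholder
    rnaseh1_table: str | None = None
    #: optional minor-allele-frequency cutoff for SNP masking; None = mask all
    maf_threshold: float | None = None
    #: also search the reverse complement of each transcript
    search_reverse_strand: bool = False
    #: "lexicographic" (default) or "weighted" composite ranking
    ranking: str = "lexicographic"
    #: weights for the optional weighted-sum ranking mode
    rank_weights: dict = field(default_factory=lambda: {
        "rnaseh1_score": 1.0, "offtargets": 1.0, "mfe": 0.2, "gc_dev": 1.0,
    })

    def with_overrides(self, **kwargs) -> "DesignConfig":
        """Return a copy with the given non-None fields replaced."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates) if updates else self


def load_config(path: str | Path | None = None, **overrides) -> DesignConfig:
    """Load a :class:`DesignConfig` from a YAML key-value file.

    Unknown keys raise ``ValueError`` so typos in threshold names do not
    silently fall back to defaults. ``overrides`` (e.g. CLI flags) win over
    file values.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} is not a key-value mapping")
        known = {f.name for f in fields(DesignConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    for key in ("species",):
        if key in values and isinstance(values[key], list):
            values[key] = tuple(values[key])
    for key in ("gc_unfavorable_low", "gc_unfavorable_high"):
        if key in values:
            values[key] = tuple(values[key])
    cfg = DesignConfig(**values)
    return cfg.with_overrides(**overrides)


def dump_config(cfg: DesignConfig, path: str | Path) -> None:
    """Write the effective configuration as YAML (reproducibility sidecar)."""
    data = {}
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        data[f.name] = list(v) if isinstance(v, tuple) else v
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
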