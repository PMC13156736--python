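"""Tier classification and composite ranking of scored candidates.

Favorable tier = the profile shared by approved gapmer drugs (GC in
[0.3, 0.6], MFE > -2, RNase H1 score < 0.2, no transcript below 4
mismatches and at most 10 at exactly 4). Unfavorable fires on any single
bad metric (MFE < -5; GC in [0.2, 0.3) or (0.6, 0.75], or outside
[0.2, 0.75] entirely; more than 10 transcripts at exactly 4 mismatches;
RNase H1 score >= 0.5) and takes precedence. Everything else is neutral.

The composite ranking is lexicographic — tier, then RNase H1 score, then
close off-target load, then MFE (higher first), then distance of GC from
the favorable-band center, then position — because no principled metric
weights exist; an optional weighted-sum mode is provided for
experimentation.
"""

from __future__ import annotations

from .candgen import GapmerCandidate
from .config import DesignConfig
from .offtarget import close_offtargets
from .seqio import DataError

TIERS = ("favorable", "neutral", "unfavorable")
_TIER_ORDER = {t: i for i, t in enumerate(TIERS)}

#: metric fields that must be populated before classification
_REQUIRED = ("gc", "mfe", "rnaseh1_score")

#: GC center of the favorable band, used as the ranking reference
GC_CENTER = 0.45


def _require_metrics(candidate: GapmerCandidate) -> None:
    for name in _REQUIRED:
        if getattr(candidate, name) is None:
            raise DataError(f"metric {name!r} unset on candidate at {candidate.start}")
    if not candidate.offtarget_counts:
        raise DataError(f"metric 'offtarget_counts' unset on candidate at {candidate.start}")


def classify(candidate: GapmerCandidate,
             cfg: DesignConfig = DesignConfig()) -> str:
    """Assign favorable / neutral / unfavorable; unfavorable wins ties."""
    _require_metrics(candidate)
    gc, mfe = candidate.gc, candidate.mfe
    score = candidate.rnaseh1_score
    mm4 = candidate.offtarget_counts.get(4, 0)
    close = close_offtargets(candidate.offtarget_counts, cfg.max_mismatches)

    lo_band, hi_band = cfg.gc_unfavorable_low, cfg.gc_unfavorable_high
    gc_bad = (
        (lo_band[0] <= gc < lo_band[1])      # [0.2, 0.3)
        or (hi_band[0] < gc <= hi_band[1])   # (0.6, 0.75]
        or gc < lo_band[0] or gc > hi_band[1]  # extrapolated extremes
    )
    if (mfe < cfg.mfe_unfavorable or gc_bad or mm4 > cfg.offtarget_mm4_max
            or score >= cfg.rnaseh1_unfavorable):
        return "unfavorable"
    if (cfg.gc_favorable_min <= gc <= cfg.gc_favorable_max
            and mfe > cfg.mfe_favorable
            and score < cfg.rnaseh1_favorable
            and close <= cfg.offtarget_close_max
            and mm4 <= cfg.offtarget_mm4_max):
        return "favorable"
    return "neutral"


def _lex_key(c: GapmerCandidate):
    return (
        _TIER_ORDER[c.tier],
        c.rnaseh1_score,
        close_offtargets(c.offtarget_counts),
        -c.mfe,
        abs(c.gc - GC_CENTER),
        c.start,
    )


def _weighted_key(c: GapmerCandidate, weights: dict):
    penalty = (
        weights.get("rnaseh1_score", 1.0) * c.rnaseh1_score
        + weights.get("offtargets", 1.0) * close_offtargets(c.offtarget_counts)
        + weights.get("mfe", 0.2) * (-c.mfe)
        + weights.get("gc_dev", 1.0) * abs(c.gc - GC_CENTER)
    )
    return (_TIER_ORDER[c.tier], penalty, c.start)


def rank(candidates: list[GapmerCandidate],
         cfg: DesignConfig = DesignConfig()) -> list[GapmerCandidate]:
    """Order classified candidates and assign ranks 1..n (deterministic:
    the start-position tie-break makes the order independent of input
    permutation)."""
    for c in candidates:
        if c.tier is None:
            c.tier = classify(c, cfg)
    if cfg.ranking == "weighted":
        key = lambda c: _weighted_key(c, cfg.rank_weights)
    else:
        key = _lex_key
    ordered = sorted(candidates, key=key)
    for i, c in enumerate(ordered, start=1):
        c.rank = i
    return ordered
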