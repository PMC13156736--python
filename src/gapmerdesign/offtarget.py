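"""Off-target search: exact gapless k-mismatch matching over a transcriptome.

BLAST's heuristic, gapped search is replaced by an exact Hamming scan: the
working criterion for an off-target ("< 4 mismatches") is a mismatch count,
which gapless Hamming distance measures exactly and testably. The search is
seed-and-extend with a pigeonhole guarantee: the window is cut into
``max_mm + 1`` disjoint seeds, so any alignment with <= max_mm mismatches
contains at least one exact seed.

Each transcript counts once, at its best (minimum) distance against every
same-length substring; the downstream off-target verdict counts transcripts
strictly below 4 mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .candgen import GapmerCandidate, reverse_complement
from .seqio import DataError

logger = logging.getLogger(__name__)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass
class SeedIndex:
    """Exact-seed lookup over a transcriptome."""

    seed_len: int
    window: int
    max_mm: int
    #: seed string -> list of (transcript index, 0-based seed start)
    seeds: dict[str, list[tuple[int, int]]]
    ids: list[str]
    encoded: list[np.ndarray]
    reverse: bool = False


def seed_length(window: int, max_mm: int) -> int:
    """Pigeonhole seed length: floor(window / (max_mm + 1))."""
    return window // (max_mm + 1)


def build_index(transcriptome: list[tuple[str, str]], window: int = 20,
                max_mm: int = 4, reverse_strand: bool = False) -> SeedIndex:
    """Index every seed-length substring of every transcript.

    With ``reverse_strand`` the reverse complement of each transcript is
    indexed too (off by default: transcripts are single-stranded).
    """
    k = seed_length(window, max_mm)
    if k < 1:
        raise ValueError(f"window {window} too small for {max_mm} mismatches")
    seeds: dict[str, list[tuple[int, int]]] = {}
    ids: list[str] = []
    encoded: list[np.ndarray] = []
    for tid, seq in transcriptome:
        seq = seq.upper()
        strands = [seq]
        if reverse_strand:
            strands.append(reverse_complement(seq))
        for strand_i, strand in enumerate(strands):
            idx = len(ids)
            ids.append(tid if strand_i == 0 else tid + "/rc")
            encoded.append(_encode(strand))
            if len(strand) < k:
                logger.warning("transcript %s shorter than seed length %d; skipped",
                               tid, k)
                continue
            for p in range(len(strand) - k + 1):
                seeds.setdefault(strand[p:p + k], []).append((idx, p))
    return SeedIndex(seed_len=k, window=window, max_mm=max_mm, seeds=seeds,
                     ids=ids, encoded=encoded, reverse=reverse_strand)


def _best_distances(site: str, index: SeedIndex) -> dict[str, int]:
    """Best Hamming distance per transcript id, capped at max_mm."""
    w, k, max_mm = index.window, index.seed_len, index.max_mm
    site_arr = _encode(site)
    best: dict[int, int] = {}
    checked: set[tuple[int, int]] = set()
    for slot in range(max_mm + 1):
        off = slot * k
        seed = site[off:off + k]
        for t_idx, p in index.seeds.get(seed, ()):  # alignment start = p - off
            start = p - off
            if start < 0 or start + w > len(index.encoded[t_idx]):
                continue
            if (t_idx, start) in checked:
                continue
            checked.add((t_idx, start))
            d = int(np.count_nonzero(
                index.encoded[t_idx][start:start + w] != site_arr))
            if d <= max_mm and d < best.get(t_idx, max_mm + 1):
                best[t_idx] = d
    out: dict[str, int] = {}
    for t_idx, d in best.items():
        tid = index.ids[t_idx].removesuffix("/rc")
        if d < out.get(tid, index.max_mm + 1):
            out[tid] = d
    return out


def count_offtargets(candidate: GapmerCandidate, index: SeedIndex,
                     target_id: str | set[str] | None = None) -> dict[int, int]:
    """Bucket counts {0..max_mm: distinct transcripts at that best distance}.

    ``target_id`` names the on-target transcript(s) to exclude (defaults to
    the candidate's gene id).
    """
    if len(candidate.target_site) != index.window:
        raise DataError(
            f"candidate window {len(candidate.target_site)} != index window {index.window}")
    if target_id is None:
        target_id = {candidate.gene_id}
    elif isinstance(target_id, str):
        target_id = {target_id}
    counts = {k: 0 for k in range(index.max_mm + 1)}
    for tid, d in _best_distances(candidate.target_site, index).items():
        if tid in target_id:
            continue
        counts[d] += 1
    return counts


def close_offtargets(counts: dict[int, int], max_mm: int = 4) -> int:
    """Number of true off-target transcripts: best distance strictly < 4."""
    return sum(v for k, v in counts.items() if k < max_mm)


def offtarget_flag(counts: dict[int, int], close_max: int = 0,
                   mm4_max: int = 10, close_unfavorable: int = 2) -> str:
    """Tier flag from bucket counts.

    Favorable: no transcript below 4 mismatches and at most 10 at exactly 4.
    Unfavorable: more than 10 at exactly 4, or more than 2 below 4.
    """
    close = close_offtargets(counts)
    mm4 = counts.get(4, 0)
    if mm4 > mm4_max or close > close_unfavorable:
        return "unfavorable_offtarget"
    if close <= close_max and mm4 <= mm4_max:
        return "favorable"
    return "neutral"


def dump_hits(candidate: GapmerCandidate, index: SeedIndex,
              target_id: str | set[str] | None = None) -> list[tuple[str, int, int, int]]:
    """BED-like hit list: (transcript, 1-based start, end, mismatches)."""
    if target_id is None:
        target_id = {candidate.gene_id}
    elif isinstance(target_id, str):
        target_id = {target_id}
    w = index.window
    site_arr = _encode(candidate.target_site)
    hits = []
    seen: set[tuple[int, int]] = set()
    for slot in range(index.max_mm + 1):
        off = slot * index.seed_len
        seed = candidate.target_site[off:off + index.seed_len]
        for t_idx, p in index.seeds.get(seed, ()):
            start = p - off
            if start < 0 or start + w > len(index.encoded[t_idx]):
                continue
            if (t_idx, start) in seen:
                continue
            seen.add((t_idx, start))
            tid = index.ids[t_idx].removesuffix("/rc")
            if tid in target_id:
                continue
            d = int(np.count_nonzero(
                index.encoded[t_idx][start:start + w] != site_arr))
            if d <= index.max_mm:
                hits.append((index.ids[t_idx], start + 1, start + w, d))
    hits.sort()
    return hits
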