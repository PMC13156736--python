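"""Candidate generation: SNP masking, sliding-window segmentation, GC.

The pre-mRNA is treated as one linear sequence (the nuclear substrate of a
gapmer ASO). Windows that overlap any annotated SNP are removed wholesale;
the survivors are enumerated with a 1-nt step, the finest "sequence
walking" granularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .seqio import DataError, SnpRecord, TargetGene

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: unset-metric sentinel distinct from a legitimate 0.0
UNSET = None


@dataclass
class GapmerCandidate:
    """One windowed target site plus its antisense oligo and metrics.

    ``start`` is 0-based on the pre-mRNA; ``target_site`` is the sense
    strand 5'->3'; ``aso_sequence`` its reverse complement (the oligo as
    synthesized, DNA alphabet). Scoring fields stay ``None`` until the
    corresponding pipeline stage fills them.
    """

    gene_id: str
    start: int
    target_site: str
    aso_sequence: str
    gc: float
    window: int = 20
    mfe: float | None = None
    rnaseh1_score: float | None = None
    offtarget_counts: dict[int, int] = field(default_factory=dict)
    homology: dict[str, float | None] = field(default_factory=dict)
    tier: str | None = None
    rank: int | None = None

    @property
    def end(self) -> int:
        return self.start + self.window


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N} (case preserved)."""
    for ch in seq:
        if ch.upper() not in "ACGTN":
            raise DataError(f"illegal character {ch!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def compute_gc(seq: str) -> float:
    """Exact G+C fraction of a candidate site (N not allowed)."""
    if not seq:
        raise DataError("cannot compute GC of an empty sequence")
    seq = seq.upper()
    if "N" in seq:
        raise DataError("cannot compute GC of a sequence containing N")
    return (seq.count("G") + seq.count("C")) / len(seq)


def allowed_window_starts(seq_len: int, window: int,
                          snps: list[SnpRecord]) -> list[int]:
    """All 0-based starts whose window [s, s+window) covers no SNP.

    A SNP at position p removes starts max(0, p-window+1) .. p.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if seq_len < window:
        logger.warning("sequence length %d shorter than window %d: no candidates",
                       seq_len, window)
        return []
    blocked = bytearray(seq_len - window + 1)
    for snp in snps:
        lo = max(0, snp.pos - window + 1)
        hi = min(snp.pos, seq_len - window)
        for s in range(lo, hi + 1):
            blocked[s] = 1
    return [s for s in range(seq_len - window + 1) if not blocked[s]]


def enumerate_candidates(gene: TargetGene, snps: list[SnpRecord] | None = None,
                         window: int = 20,
                         maf_threshold: float | None = None) -> list[GapmerCandidate]:
    """Enumerate SNP-free, N-free sliding-window candidates (step 1 nt).

    ``maf_threshold``, when set, masks only SNPs at or above that minor
    allele frequency (records without a frequency are always masked).
    """
    snps = snps or []
    if maf_threshold is not None:
        snps = [s for s in snps if s.maf is None or s.maf >= maf_threshold]
    starts = allowed_window_starts(len(gene), window, snps)
    candidates = []
    n_dropped = 0
    for s in starts:
        site = gene.sequence[s:s + window]
        if "N" in site:
            n_dropped += 1
            continue
        candidates.append(GapmerCandidate(
            gene_id=gene.gene_id,
            start=s,
            window=window,
            target_site=site,
            aso_sequence=reverse_complement(site),
            gc=compute_gc(site),
        ))
    if n_dropped:
        logger.info("dropped %d window(s) containing N in gene %s",
                    n_dropped, gene.gene_id)
    return candidates
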