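"""End-to-end design pipeline: candidates -> metrics -> tiers -> ranking."""

from __future__ import annotations

import logging

from . import (candgen, classify_rank, homology as homology_mod, offtarget,
               rnaseh1, structure)
from .candgen import GapmerCandidate
from .config import DesignConfig
from .seqio import OrthologSet, SnpRecord, TargetGene

logger = logging.getLogger(__name__)


def design(gene: TargetGene,
           snps: list[SnpRecord] | None = None,
           transcriptome: list[tuple[str, str]] | None = None,
           orthologs: OrthologSet | None = None,
           cfg: DesignConfig = DesignConfig()) -> list[GapmerCandidate]:
    """Run the full gapmer design pipeline, returning ranked candidates.

    Stages: SNP masking + sliding-window enumeration, self-structure MFE,
    off-target bucket counts, RNase H1 score, per-species homology, tier
    classification, composite ranking.
    """
    candidates = candgen.enumerate_candidates(
        gene, snps, window=cfg.window, maf_threshold=cfg.maf_threshold)
    logger.info("gene %s: %d candidate window(s)", gene.gene_id, len(candidates))

    nn_table = structure.default_nn_table()
    h1_table = rnaseh1.load_table(cfg.rnaseh1_table)
    index = None
    if transcriptome:
        index = offtarget.build_index(
            transcriptome, window=cfg.window, max_mm=cfg.max_mismatches,
            reverse_strand=cfg.search_reverse_strand)
    orthologs = orthologs or OrthologSet()

    for cand in candidates:
        cand.mfe = structure.fold_mfe(cand.aso_sequence, nn_table)
        cand.rnaseh1_score = rnaseh1.score(cand, h1_table)
        if index is not None:
            cand.offtarget_counts = offtarget.count_offtargets(cand, index)
        else:
            cand.offtarget_counts = {k: 0 for k in range(cfg.max_mismatches + 1)}
        cand.homology = homology_mod.homology_profile(cand, orthologs, cfg.species)

    ranked = classify_rank.rank(candidates, cfg)
    tiers = {t: sum(1 for c in ranked if c.tier == t) for t in classify_rank.TIERS}
    logger.info("tiers: %s", tiers)
    return ranked


def filter_conserved(candidates: list[GapmerCandidate], species: list[str],
                     min_identity: float = 1.0) -> list[GapmerCandidate]:
    """Keep candidates conserved in every named species."""
    return [c for c in candidates
            if all(homology_mod.conserved_in(c, sp, min_identity) for sp in species)]
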