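"""Deterministic synthetic inputs: genes, SNPs, decoy transcripts, orthologs.

Every generator is a pure function of its seed and parameters. A single
global seed fans out to per-fixture child seeds as the lowest 31 bits of
``sha256("{seed}:{label}")``, so adding a fixture never reshuffles existing
ones. Planted structure (SNP positions, decoy distances, divergence) is
verified against a brute-force check at generation time.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqio import (OrthologSet, SnpRecord, TargetGene, write_fasta,
                    write_snps_vcf)

BASES = np.array(list("ACGT"))


def child_seed(seed: int, label: str) -> int:
    """Deterministic fan-out: lowest 31 bits of sha256('{seed}:{label}')."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def make_gene(seed: int, length: int = 600, gc_target: float = 0.5,
              gene_id: str = "synthgene") -> TargetGene:
    """Seeded pseudorandom pre-mRNA with realized GC within 0.02 of target.

    The G+C count is fixed at ``round(length * gc_target)`` and those
    positions are shuffled in, so the realized fraction is exact up to the
    1/length grid.
    """
    if length < 20:
        raise ValueError(f"gene length {length} below the 20-nt window")
    if not 0.0 < gc_target < 1.0:
        raise ValueError(f"gc_target {gc_target} outside (0, 1)")
    n_gc = round(length * gc_target)
    if abs(n_gc / length - gc_target) > 0.02:
        raise ValueError(
            f"gc_target {gc_target} unreachable within 0.02 at length {length}")
    rng = np.random.default_rng(seed)
    bases = np.empty(length, dtype="<U1")
    gc_positions = rng.choice(length, size=n_gc, replace=False)
    mask = np.zeros(length, dtype=bool)
    mask[gc_positions] = True
    bases[mask] = rng.choice(["G", "C"], size=n_gc)
    bases[~mask] = rng.choice(["A", "T"], size=length - n_gc)
    return TargetGene(gene_id=gene_id, sequence="".join(bases))


def plant_snps(gene: TargetGene, seed: int,
               positions: list[int] | None = None,
               density: float | None = None) -> list[SnpRecord]:
    """SNPs at explicit positions, or at a seeded per-base density.

    ref is always the actual gene base; alt a different seeded base.
    """
    rng = np.random.default_rng(seed)
    if positions is None:
        if density is None:
            raise ValueError("give either positions or density")
        positions = [int(p) for p in np.nonzero(rng.random(len(gene)) < density)[0]]
    else:
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate SNP positions")
        for p in positions:
            if not 0 <= p < len(gene):
                raise ValueError(f"SNP position {p} outside gene of length {len(gene)}")
    snps = []
    for i, pos in enumerate(sorted(positions)):
        ref = gene.sequence[pos]
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[int(rng.integers(3))]
        snps.append(SnpRecord(pos=pos, ref=ref, alt=alt, rsid=f"rs{seed % 1000}{i:03d}"))
    for s in snps:  # generation-time verification
        assert gene.sequence[s.pos] == s.ref
    return snps


def _best_hamming(site: str, transcript: str) -> int:
    site_arr = np.frombuffer(site.encode(), dtype=np.uint8)
    t_arr = np.frombuffer(transcript.encode(), dtype=np.uint8)
    windows = sliding_window_view(t_arr, len(site))
    return int((windows != site_arr).sum(axis=1).min())


def plant_decoys(gene: TargetGene, candidate_start: int, seed: int,
                 distances: list[int], window: int = 20,
                 flank: int = 60) -> list[tuple[str, str]]:
    """Decoy transcripts, one per requested Hamming distance.

    Each decoy is a seeded random background with an embedded copy of the
    candidate target site mutated at exactly ``d`` positions; the best
    Hamming distance of the whole decoy to the site is re-verified to equal
    ``d`` by a brute-force scan (backgrounds are redrawn on the rare
    accidental closer match).
    """
    site = gene.sequence[candidate_start:candidate_start + window]
    if len(site) != window:
        raise ValueError(f"candidate window [{candidate_start}, +{window}) outside gene")
    rng = np.random.default_rng(seed)
    decoys = []
    for i, d in enumerate(distances):
        if not 0 <= d <= window:
            raise ValueError(f"distance {d} outside 0..{window}")
        for _attempt in range(100):
            mutated = list(site)
            for p in rng.choice(window, size=d, replace=False):
                choices = [b for b in "ACGT" if b != site[p]]
                mutated[p] = choices[int(rng.integers(3))]
            left = "".join(rng.choice(BASES, size=flank))
            right = "".join(rng.choice(BASES, size=flank))
            decoy = left + "".join(mutated) + right
            if _best_hamming(site, decoy) == d:
                break
        else:
            raise RuntimeError(f"could not plant a clean distance-{d} decoy")
        decoys.append((f"decoy_mm{d}_{i}", decoy))
    return decoys


def make_transcriptome(gene: TargetGene, seed: int, n_random: int = 20,
                       length: int = 300) -> list[tuple[str, str]]:
    """The target gene plus seeded random background transcripts."""
    rng = np.random.default_rng(seed)
    records = [(gene.gene_id, gene.sequence)]
    for i in range(n_random):
        records.append((f"tx{i:03d}", "".join(rng.choice(BASES, size=length))))
    return records


def make_orthologs(gene: TargetGene, seed: int,
                   divergence: dict[str, float]) -> OrthologSet:
    """Per-species orthologs: the gene with seeded substitutions at the
    given per-base rate (0 -> identical ortholog)."""
    sequences = {}
    for species in sorted(divergence):
        rate = divergence[species]
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"divergence {rate} for {species} outside [0, 1)")
        rng = np.random.default_rng(child_seed(seed, f"ortholog:{species}"))
        bases = list(gene.sequence)
        hits = np.nonzero(rng.random(len(bases)) < rate)[0]
        for p in hits:
            choices = [b for b in "ACGT" if b != bases[p]]
            bases[p] = choices[int(rng.integers(3))]
        seq = "".join(bases)
        assert sum(a != b for a, b in zip(seq, gene.sequence)) == len(hits)
        sequences[species] = seq
    return OrthologSet(sequences=sequences)


def write_bundle(out_dir: str | Path, seed: int = 1, length: int = 600,
                 gc_target: float = 0.5, snp_density: float = 0.01,
                 n_background: int = 20,
                 divergence: dict[str, float] | None = None) -> dict[str, Path]:
    """Emit a complete synthetic input bundle (FASTA/VCF) for the CLI."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene = make_gene(child_seed(seed, "gene"), length, gc_target)
    snps = plant_snps(gene, child_seed(seed, "snps"), density=snp_density)
    transcriptome = make_transcriptome(gene, child_seed(seed, "transcriptome"),
                                       n_random=n_background)
    if divergence is None:
        divergence = {"monkey": 0.02, "mouse": 0.05, "rat": 0.05,
                      "rabbit": 0.04, "pig": 0.04, "guinea_pig": 0.06}
    orthologs = make_orthologs(gene, child_seed(seed, "orthologs"), divergence)
    paths = {
        "gene": out / "gene.fa",
        "snps": out / "snps.vcf",
        "transcriptome": out / "transcriptome.fa",
        "orthologs": out / "orthologs.fa",
    }
    write_fasta([(gene.gene_id, gene.sequence)], paths["gene"])
    write_snps_vcf(snps, gene.gene_id, paths["snps"])
    write_fasta(transcriptome, paths["transcriptome"])
    write_fasta(sorted(orthologs.sequences.items()), paths["orthologs"])
    return paths
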