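# gapmerdesign

Rational sequence design of **gapmer antisense oligonucleotides (ASOs)** —
short single-stranded nucleic acids with a central DNA "gap" and chemically
modified wings that silence a gene by recruiting RNase H1 to cleave the
target RNA. Given a target pre-mRNA, an annotated SNP table, a transcriptome
and ortholog sequences for the common preclinical species, `gapmerdesign`
produces a ranked table of candidate 20-mer target sites scored by the
determinants of gapmer efficacy and safety:

- **SNP avoidance** — windows overlapping any annotated variant are removed
  (a single mismatch can abolish efficacy in part of the patient population);
- **GC content** — exact G+C fraction of the 20-mer site;
- **self-structure MFE** — minimum free energy of the oligo's own secondary
  structure, from an internal Zuker-style nearest-neighbor dynamic program
  (higher = less self-structure, kcal/mol);
- **off-target load** — per mismatch level 0–4, the number of distinct
  non-target transcripts the site matches, via an exact gapless seed-and-extend
  Hamming search (an *off-target* is a transcript at **< 4 mismatches**);
- **RNase H1 cleavage preference** — mean position-weight score over the
  gap-complementary decamer (lower = higher predicted cleavage);
- **cross-species homology** — best ungapped identity of the site in each
  ortholog (1.0 = perfectly conserved), for translation into wild-type
  animal models.

Candidates are tiered **favorable** (GC in [0.3, 0.6], MFE > −2,
RNase H1 score < 0.2, no transcript below 4 mismatches and ≤ 10 at exactly 4 —
the profile shared by approved gapmer drugs), **unfavorable** (any of:
MFE < −5, GC in [0.2, 0.3) or (0.6, 0.75] or beyond, > 10 transcripts at
exactly 4 mismatches, RNase H1 score ≥ 0.5) or **neutral**, then ranked by a
deterministic composite order. The chemistry module renders 5-10-5
2′-MOE / full-PS annotation, GalNAc conjugation, and the 5-10-5 MOE →
3-10-3 cEt lead conversion (trim two bases per end; the gap decamer is
untouched).

## Worked example

Everything runs on synthetic inputs generated by the package itself — no
downloads:

```bash
gapmerdesign fixtures --out-dir demo --seed 1 --length 300
gapmerdesign design \
    --gene demo/gene.fa --snps demo/snps.vcf \
    --transcriptome demo/transcriptome.fa --orthologs demo/orthologs.fa \
    --out demo/report.tsv
```

which logs

```
INFO gapmerdesign.pipeline: gene synthgene: 216 candidate window(s)
INFO gapmerdesign.pipeline: tiers: {'favorable': 0, 'neutral': 71, 'unfavorable': 145}
INFO gapmerdesign: wrote 216 row(s) to demo/report.tsv
```

216 = the 281 sliding windows of a 300-nt gene minus those overlapping a
planted SNP. The top of `demo/report.tsv` (selected columns):

| position | aso_sequence | gc | mfe | rnaseh1_score | homology_mouse | tier | rank |
|---|---|---|---|---|---|---|---|
| 131 | AGCAACGTGGAAACAGAGGT | 0.5000 | 0.0000 | 0.3340 | 0.9500 | neutral | 1 |
| 228 | TACTAGTCGCAACTGGGGAA | 0.5000 | 0.0000 | 0.3500 | 0.9000 | neutral | 2 |
| 207 | TATTTCGCATCGACGCTAGC | 0.5000 | 0.0000 | 0.3600 | 0.9500 | neutral | 3 |

`position` is the 1-based start of the target site on the pre-mRNA;
`aso_sequence` is the oligo as synthesized (reverse complement of the site,
5′→3′ DNA). These leads have no self-structure (MFE 0.0), mid-range GC, no
off-target below 5 mismatches, and 90–95 % identity in the synthetic mouse
ortholog. No candidate reaches the favorable tier here because the shipped
RNase H1 table is a synthetic placeholder whose scores rarely drop below the
0.2 cutoff — supply a table derived from experimental cleavage data via the
`rnaseh1_table` config key for real designs.

The other subcommands expose the standalone tools: `homology` (per-window
identity profile), `snp` (variant query over a 1-based interval),
`offtarget` (bucket counts plus an optional per-hit dump) and `fixtures`.
`--require-species mouse` keeps only perfectly conserved candidates;
`--cet` additionally emits the 3-10-3 cEt conversion of favorable leads.

As a library:

```python
from gapmerdesign import DesignConfig, design
from gapmerdesign.fixtures import make_gene, make_transcriptome

gene = make_gene(seed=1, length=300)
ranked = design(gene, transcriptome=make_transcriptome(gene, seed=1))
print(ranked[0].aso_sequence, ranked[0].tier)
```

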