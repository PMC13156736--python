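# Methods

## Scope and model

`gapmerdesign` treats the target pre-mRNA as one linear sense-strand
sequence — the nuclear substrate of a gapmer ASO — and evaluates every
20-nt window (the target site of a canonical 5-10-5 gapmer) that survives
SNP masking. All internal coordinates are 0-based half-open; file formats
(VCF `POS`, the report `position` column) are 1-based inclusive, converted
exactly at the I/O boundary.

### SNP masking and segmentation

Any window overlapping an annotated variant position is removed wholesale:
masking is all-or-nothing per window, with an optional minor-allele-frequency
cutoff (`maf_threshold`, default off) to ignore very rare variants. The
sliding-window step is 1 nt — the finest "sequence walking" granularity —
so a SNP-free, N-free gene of length L yields exactly L − 19 candidates.
Windows containing N are dropped (logged): undetermined bases cannot be
scored. A SNP ref allele that disagrees with the gene FASTA is a warning,
not an error; masking needs only the position, and variant extracts and
user FASTAs may come from different builds.

### Self-structure MFE

The structure score is the minimum free energy of the *oligo's own*
secondary structure (not target accessibility, which is a different and
much harder prediction), computed as DNA at 37 °C — the molecule being
synthesized is modified DNA. The folding model is a Zuker-style dynamic
program over:

- nearest-neighbor Watson-Crick stack energies (ΔG°37),
- hairpin loops of size ≥ 3 nt,
- bulge and internal loops up to 30 nt,
- **no multibranch loops** — a 20-mer cannot meaningfully form a
  multiloop, and the restricted class admits an exact brute-force oracle:
  the test suite enumerates *every* admissible pair set for oligos up to
  14 nt, scores them with a standalone scorer, and requires exact equality
  with the DP.

Numerical choices: all energies are handled as integer tenths of a kcal/mol
(0.1 kcal/mol resolution), so DP arithmetic is exact; DP ties are broken
toward fewer base pairs; hairpin loops above 30 nt reuse the size-30
penalty while oversized bulge/internal loops are disallowed; MFE is clamped
at 0.0 (an oligo with no stabilizing structure reports exactly 0);
sequences under 8 nt return 0.0 with a warning. The parameter set ships as
a data file (`data/nn_params.tsv`, checksummed in tests) with
SantaLucia-style unified DNA stack values rounded to 0.1 kcal/mol and
log-extrapolated loop penalties past size 10; it is replaceable data, not
code — the DP is the artifact.

### Off-target search

The off-target criterion is a mismatch count ("fewer than 4 mismatches"),
so the search is an **exact gapless Hamming scan**, not a heuristic local
aligner: results are reproducible and provable. Divergence from gapped,
E-value-driven BLAST hit lists is expected and intentional — gapped hits
with indels are not counted, because a 20-mer ASO tolerates no indels in
its binding site. The implementation is seed-and-extend with a pigeonhole
guarantee: the 20-mer is cut into `max_mm + 1 = 5` disjoint 4-nt seeds, so
any alignment with ≤ 4 mismatches must contain one exact seed; each seed
hit is extended and verified by full Hamming comparison. Each transcript
counts once, at its best distance (a transcript with both a 2-mismatch and
a 4-mismatch site is a 2-mismatch off-target). Distinct FASTA records are
counted as distinct "genes"; isoform collapse is the user's preprocessing.
Transcripts are treated as single-stranded; indexing the reverse complement
too is available behind `search_reverse_strand` (default off). The suite
checks the counter against an all-substring brute-force scan and plants
1,000 seeded decoys to verify nothing at distance ≤ 4 is ever missed.

### RNase H1 cleavage preference

The score is the mean, over the scored region of the target site, of a
per-(position, base) weight in [0, 1]; lower = higher predicted cleavage.
The scored region defaults to the **central 10 nt** — the stretch
complementary to the DNA gap, which is what recruits RNase H1 — but the
region length is declared by the weight table itself, so full-window tables
work unchanged. The mean (rather than sum or product) keeps the score on
the same [0, 1] scale as its thresholds regardless of region length. Two
tables ship: a uniform null (all 0.25) and a clearly labelled synthetic
placeholder; a table derived from experimental cleavage data is supplied
by the user (`rnaseh1_table` config key). The functional form is this
package's own design choice and is deliberately swappable.

### Cross-species homology

Per candidate and species, the reported value is the best **ungapped**
identity of the 20-mer site over every same-length ortholog substring
(1.0 = the site occurs verbatim). Gapped alignment would overstate
translational compatibility, since an ASO binding site tolerates no
indels. An absent ortholog reports NA and counts as non-conserved in
filtering; the conservation filter defaults to perfect identity
(`min_identity = 1.0`), matching how cross-species leads are chosen for
in vivo work. Homology is per-site, not gene-region averaged.

### Tiers and ranking

Favorable requires **all** of: GC in [0.3, 0.6] (closed interval), MFE > −2
(strict), RNase H1 score < 0.2 (strict), zero transcripts below 4
mismatches and at most 10 at exactly 4. Unfavorable fires on **any** of:
MFE < −5 (strict), GC in [0.2, 0.3) or (0.6, 0.75] — extended to everything
below 0.2 or above 0.75, since more extreme compositions cannot be better —
more than 10 transcripts at exactly 4 mismatches, or RNase H1 score ≥ 0.5.
Unfavorable takes precedence; everything else is neutral. Boundary
semantics keep GC 0.3 and 0.6 favorable and MFE −2/−5 and score 0.2
neutral-side, i.e. every printed inequality is strict exactly as written.

The composite ranking is lexicographic — tier, RNase H1 score ascending,
close off-target count ascending, MFE descending, |GC − 0.45| ascending,
then start position — because no principled weighting of the metrics
exists; a lexicographic order is reproducible and explainable, and the
final position key makes ranking a deterministic total order independent
of input permutation. A weighted-sum mode (`ranking: weighted`) is
available for experimentation.

### Chemistry

`GapmerPattern` records wing/gap/wing sizes, wing chemistry (2′-MOE or
2′-cEt), backbone (PS/PO) and conjugate (GalNAc or none). The annotation
format — optional `GalNAc-` prefix, `[MOE]`/`[cEt]` header, lowercase wings,
uppercase DNA gap, `*` for phosphorothioate linkages — is this package's
own, since no community standard covers gapmer chemistry strings; it is
invertible, and a JSON rendering is provided. The 5-10-5 MOE → 3-10-3 cEt
conversion removes two bases at each end of the 20-mer, preserving the gap
decamer and the site center (start shifts by +2); the inverse extension
(for comparing a 16-mer cEt reference as a 20-mer MOE) requires the two
flanking target bases per side as input.

## Synthetic data

The fixtures module generates every input deterministically: genes with an
exact G+C count placed at seeded random positions (realized GC within 0.02
of target), SNPs whose ref always matches the gene, decoy transcripts with
an embedded site copy mutated at *exactly* d positions (re-verified by
brute force at generation time), and orthologs with seeded per-base
substitutions. One global seed fans out per fixture as the lowest 31 bits
of `sha256("{seed}:{label}")`, so adding fixtures never reshuffles existing
ones. Default generation parameters — 600-nt genes at GC 0.5, SNP density
0.01/nt, 20 background transcripts, per-species divergences of 2–6 % —
are a deliberately small but structurally faithful stand-in for a real
locus.

What the fixtures do **not** emulate: splice architecture and exon/intron
composition bias, codon structure, empirical SNP spectra and allele
frequencies, transcriptome-scale paralog families, and real ortholog indel
patterns. Passing tests therefore demonstrate that the algorithms are
correct on their own terms (oracle equivalence, planted-structure
recovery, boundary behavior), not that the default thresholds are optimal
for any particular real gene.

## Problem sizes and determinism

The shipped test suite and acceptance sweeps use genes of 60–300 nt,
transcriptomes of ≤ 50 records, folding oracle panels of 200 oligos of
8–14 nt, and 1,000 planted decoys — sizes chosen so every oracle is
exhaustive and the whole suite runs in seconds while exercising each code
path at full fidelity; the algorithms themselves scale to full-length
pre-mRNAs (the DP is quartic only in the 20-nt window, the off-target index
is linear in transcriptome size). Every stochastic step is seeded;
design runs are byte-identical across reruns and input record
permutations.

## Known limitations

- Self-structure MFE ignores modified-sugar (MOE/cEt) and phosphorothioate
  energetics and ASO:RNA heteroduplex thermodynamics.
- Target accessibility (structure of the mRNA around the site) is not
  modeled.
- Off-target counting is gapless and unweighted by expression; it also
  cannot model cleavage competence of a mismatched heteroduplex.
- The shipped RNase H1 weights are synthetic placeholders; tier calls that
  depend on the RNase H1 score are only as good as the user-supplied table.
- Sequence-motif/chemistry toxicity is out of scope; experimental
  validation remains indispensable.
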