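# Methods

`haplodiff` analyses the differences between the two haploid genomes of a
single dikaryotic (two-nucleus) fungal strain and the expression consequences
of those differences.  This note records the models, the numerical choices,
and what the bundled synthetic-data generator does and does not emulate.

## Variant model

A variant is a REF/ALT pair anchored on haplotype A with the VCF anchor-base
convention.  Its *affected base size* is `len(ALT) - len(REF)`:

* size 0 with single-base alleles — SNP;
* 0 < |size| < 50 — insertion/deletion (indel);
* |size| >= 50 — structural variation (INS_SV / DEL_SV).

The 50-bp boundary follows the common SV convention; the size of exactly
50 bp, which the verbal "shorter than 50 / longer than 50" rule leaves
unassigned, is classified as an SV.  Equal-length multi-base substitutions
are rejected rather than silently decomposed.

A variant's *footprint* is its reference interval `[pos, pos + max(len(REF),
1) - 1]`; an insertion's footprint is its single anchor base, because the
inserted sequence has no reference coordinates.  Location labels
(exon/intron/intergenic) use the priority exon > intron > intergenic when a
footprint touches several feature types — made explicit because a long
deletion can straddle boundaries.

Gene conservation uses the genomic span of the gene (not the spliced
length): overlap bases are counted after merging variant footprints, so a
base covered by two variants counts once; whether to merge is a package
decision, as is counting against the unspliced span.  A gene is *conserved*
at overlap fraction <= 0.2%, *variable* at >= 2%, *intermediate* otherwise.
Window densities tile each contig with fixed nonoverlapping windows (default
50 kb, last window short), assigning each variant to the window containing
its anchor.

## Allelome resolution

All protein comparisons are global (Needleman–Wunsch) alignments under
BLOSUM62 with affine gaps (open 11, extend 1).  *Identity* is the fraction
of matching columns among columns where both sequences place a residue;
*coverage* is that aligned length divided by the longer sequence's length
(so a short perfect fragment has high identity but low coverage).
"Similarity >= 90%" in the duplication rule is implemented as alignment
identity >= 0.90, a deliberate dialect choice (substitution-matrix
"positives" would be more permissive).  Threshold comparisons carry a 1e-9
slack so that ratios of small integers landing exactly on a threshold are
not lost to floating-point rounding.

* **Haplotype-specific genes**: a gene with no hit in the opposite proteome
  at identity >= 0.5 and coverage >= 0.5 (both directions).  These
  permissive thresholds are an alignment-based surrogate for a BLAST
  E-value screen; a length-ratio prefilter (a cheap upper bound on
  coverage) skips hopeless alignments.
* **Allelic pairs**: candidates at identity >= 0.85 are matched one-to-one
  greedily in descending (identity, score) order with a lexicographic
  gene-id tie-break.  The published analysis additionally consulted a
  phylogenetic tree; tree building is out of scope here, and the greedy
  matching is the deterministic stand-in that preserves the one-to-one
  semantics.  Raising the identity floor can only shrink the pair set
  (property-tested).
* **Duplication groups**: an undirected graph with an edge for every pair
  meeting coverage >= 0.5 and identity >= 0.90; groups are connected
  components with >= 2 members.
* **Tandem clusters**: within a group and contig, maximal runs of members
  separated by at most `max_intervening` non-member genes (default 1,
  reflecting an essentially contiguous observed cluster; configurable).

## Differential expression and intersection schemes

The package's contribution here is the fixed decision rule and the
intersection logic, not the test statistic.  A gene is a DEG when
|log2 fold change| >= 1 and P <= 1e-3; no additional multiple-testing
correction is applied on top of this fixed rule.  The per-gene test is
pluggable:

* `deseq2` (default) — the DESeq2 Wald test via pydeseq2, i.e. the standard
  negative-binomial GLM with shared dispersion trend.  At the calibration
  conditions used in the tests (8-fold induction, NB dispersion 0.05, three
  replicates, mean 200) it reaches sensitivity ~1.0 with a null deg rate of
  ~0.
* `welch` — median-of-ratios library normalization, then a two-sided Welch
  t-test on log2(normalized count + 1) per gene.  With three replicates the
  per-gene variance estimate has ~4 degrees of freedom and the test is
  severely underpowered at P <= 1e-3 (sensitivity ~0.5 under the same
  conditions); it is kept as a dependency-light option and its *null*
  calibration is still verified.
* `external` — ingest any tool's per-gene (log2FC, p) table and apply only
  the threshold rule.

Fold changes are oriented condition-B-over-condition-A; the Welch route adds
a pseudocount of 1 before taking logs so zero counts are defined.

Condition schemes operate on DEG *sets*.  `intersect_k_of_n` returns genes
present in at least k of n sets (k = n is plain intersection; anti-monotone
in k).  The **temperature scheme** applies k-of-n over the per-carbon-source
25-vs-35 comparisons (six sources; k = 6 strict, k = 5 relaxed, so the
relaxed set always contains the strict one).  The **carbon scheme**
intersects each of the 15 carbon-pair comparisons across the two
temperatures and unions the 15 per-pair intersections; because the verbal
description admits more than one pooling, the per-pair sets are emitted
alongside the union so any alternative reading remains recoverable.

## Allele-specific expression

For one allelic pair, expression per allele in one condition is

    norm_X = mean depth of allele X over SNP loci and replicates
             / sum of the condition's replicate library sizes  x 1e6

where the SNP loci are the positions distinguishing the two alleles and a
library size is a sample's total read count (column sum of the count
matrix — "total read count" is not otherwise defined, so the column sum is
the package's reading).  Dividing by the sum rather than the mean of the
replicate library sizes differs only by the replicate count and cancels in
every fold ratio, so dominance calls are insensitive to that choice.  A pair
with zero distinguishing loci is reported *unquantifiable*, not an error.

An allele is *dominant* when its normalized value is strictly higher in
every usable condition; conditions where both values are zero are excluded,
and any direction flip yields "none".  The reported `min_fold` is the
smallest dominant/other ratio across conditions (the "at least x-fold"
readout).

## In-silico PCR and clone assignment

Primers are IUPAC strings; matching is exact outside degenerate positions
(strictest reading of a protocol that states no mismatch allowance; a
mismatch budget is configurable).  Products require the forward primer on
one strand and the reverse primer's reverse complement downstream on the
same strand within `max_product` bases; both orientations are scanned, all
products are reported, and product length counts both primer footprints (the
standard convention — relevant because the printed amplicon length is
reported without a definition).  Clones are assigned to the arg-max-identity
reference under a global nucleotide alignment (match 2, mismatch -3, gap
open 5, extend 2); a top-two tie within 1e-6 is flagged ambiguous and
excluded from the tally.

## The synthetic diploid generator

The generator emulates the object of study — two separately assembled
haplotypes of one strain — at a scale where everything is exactly scorable:

* **Ancestral sequence** is i.i.d. at the configured GC content (default
  0.52); there is no repeat structure, so nothing downstream is tested
  against repeat-induced artifacts.
* **Genes** are non-overlapping, single- or two-exon models with random
  protein products (reverse-translated so CDSs have no internal stops);
  default 60 background genes on ~1 Mb for the full-size world.
* **Variant densities** default to SNP 8e-3/bp, indel 8e-4/bp, SV 4e-5/bp —
  set to reproduce the order of magnitude of an intrastrain haplotype
  comparison (roughly 3e5 SNPs over a 40-Mb genome); they are configuration,
  not claims.  Counts are Poisson in the genome length; placement is
  rejection-sampled so footprints never overlap (1-bp margins) and never
  split a planted primer site.
* **Deliberate placement**: length-changing variants go only to intergenic
  and intronic sequence, and exonic SNPs are resampled so they never create
  stop codons.  This keeps haplotype-B proteins alignable, which makes
  haplotype-specific-gene and allelic-pair recovery exact; it also means the
  generator does *not* emulate frameshifts, broken genes, or exonic SVs —
  the classifier's handling of exon-overlapping SVs is exercised with
  hand-built fixtures instead.  SVs are insertions/deletions only (no
  inversions or translocations), matching the classes the analysis tallies.
* **Haplotype-specific genes** are created by deleting a gene from the
  opposite haplotype (emitted as a deletion SV) or inserting a new gene into
  haplotype B (an insertion SV); the gene's absence is therefore visible in
  both the annotation and the variant set.
* **The tandem family** (default 4 copies, 400-residue proteins, plus
  strand, consecutive on contig 1 in both haplotypes) is diverged at the
  protein level with disjoint mutated positions: each copy carries
  `paralog_divergence/2 x length` private substitutions, so every copy pair
  differs at exactly `paralog_divergence` of its sites (default 10%,
  i.e. pairwise identity exactly 0.90).  The haplotype-B alleles share one
  derived mutation set of `allelic_divergence x length` positions and
  residues (default 2%), like a lineage-specific haplotype: allelic identity
  is exactly 0.98 for every copy and within-haplotype paralog identity is
  symmetric between haplotypes (with per-copy independent allelic sets, the
  B-side paralogs would differ at paralog + 2 x allelic sites and fall below
  the 0.90 duplication threshold).  Codon-level differences between the A
  and B alleles are emitted as individual SNPs — these are the ASE loci.
  Every copy embeds the degenerate primer pair flanking a 563-bp amplicon at
  a fixed CDS offset; primer footprints are excluded from all mutation, and
  at least 3 paralog and 2 allelic substitutions per copy are forced into
  the amplicon interior so the eight reference amplicons are mutually
  distinguishable (>= 2 nt apart).
* **Expression** is negative-binomial (dispersion a, variance m + a m^2;
  default a = 0.05) around per-gene means (lognormal around 200 for
  background genes, 200 for family copies), with `induction_factor`
  (default 8) applied to induced genes in the induced condition (default
  35C, 3 replicates per condition).  **Allelic depths**: each SNP locus's
  total depth is NB around the pair's condition mean times
  `ase_depth_scale` (default 1, i.e. ~200x at baseline and ~1600x under
  induction) and is split between alleles binomially with probability
  `bias/(1+bias)`.  Modeling each locus at the pair's full expression depth
  (rather than dividing the expression across loci) matches the coverage
  regime the estimator is specified for (>= 50x per locus).  Because the
  binomial split conditions on the locus total, replicate-level
  overdispersion cancels from the allele ratio, which is why dominance
  directions are recovered in 100/100 seeded runs at the default biases
  (hapA/hapB = 1/1.5, 1/1.2, 1.2, 1.34 — the outer copies mirroring the
  observed "at least 1.5-fold" and "at least 1.34-fold" dominances).
* **Clone sequencing** draws a configurable number of clones (default 56)
  multinomially over the eight reference amplicons, with the observed clone
  proportions (7:19:1:0:0:0:20:9) as default weights; clones are exact
  reference copies (no sequencing-error model).

What passing tests on this generator do **not** show: robustness to repeats,
alignment/calling artifacts, frameshifted or partially broken gene models,
reference bias in allelic read depth, or PCR/cloning bias — all of which
real data contain.  The generator's determinism contract (identical config
and seed give byte-identical outputs) is itself under test.

## Problem sizes used in the checks

Desk-scale worlds keep the full default suite under half a minute and the
acceptance script under a minute on one core: a 1-Mb world at default
densities for variant-class recovery; a 200-kb, 34-gene world for allelome,
amplicon and ASE recovery (100 expression redraws); a 1-Mb, 304-gene world
with 50 planted 8-fold genes for DEG calibration.  The analysis drivers
under `analysis/` use a 300-kb, 44-gene world.

## Known limitations

* The DEG engines are standard tests, not a reimplementation of any
  specific published workflow version; numerical results on real data will
  differ from a particular DESeq2 release in the usual small ways.
* Greedy identity matching can in principle differ from a tree-aware
  pairing when paralog and allelic divergences are close; the generator's
  regime (allelic divergence well below paralog divergence) avoids this,
  real families need not.
* `insilico_pcr` scans with exact degenerate matching; it does not model
  primer thermodynamics, 3'-end sensitivity, or amplification efficiency.
* TPM is provided for expression-level reporting, but fold-change readouts
  in small simulated gene universes use median-of-ratios normalization
  because per-sample TPM rescaling distorts folds when induced genes are a
  large fraction of the transcriptome.
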