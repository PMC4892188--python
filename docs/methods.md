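# Methods

This note describes, in the package's own terms, what each analysis
stage computes and why. All constants named here are defaults of
`PipelineConfig` / `CohortSpec` / `SegmentationParams` and can be
overridden.

## 1. Call classification and filtering (`hemivar.calls`)

Every emitted genotype call carries a normalized Phred-scaled genotype
likelihood triple PL = (ref, het, alt), minimum 0. With a confidence
threshold T = 70 Phred, the triple is assigned to exactly one of seven
classes, checked in order:

1. all three ≤ T → *indeterminable* (no genotype is confidently
   excluded);
2. alt = 0, ref > T and het > T → *confident hom-alt*;
3. alt = 0, het ≤ T → *low-confidence hom-alt*;
4. het = 0, ref > T and alt > T → *confident het*;
5. het = 0, ref ≤ T or alt ≤ T → *low-confidence het*;
6. ref = 0, alt > T → *likely reference*;
7. otherwise → *unclassified*.

Inside a hemizygous deletion only one haplotype exists, so the catalog
keep rule is deliberately asymmetric: a call is kept iff **alt = 0 and
ref > T**. The het likelihood is not consulted, because a paralog-
contaminated but real variant site can show an intermediate het
likelihood; requiring het > T would discard it, while the hom-ref
likelihood alone already certifies a non-reference genotype.

Filtering removes, in order: calls in segmental duplications (never
interpretable), likely-reference emissions, indeterminable calls, and —
inside the typed deletion — calls failing the keep rule (heterozygous
classes and everything else). Every removal is recorded with its reason
in a per-call ledger.

## 2. Deletion typing (`hemivar.deletions`)

Two independent evidence tracks are computed per patient:

- **Coverage bins**: mean read depth in non-overlapping 100-bp bins;
  bins overlapping a segmental duplication are flagged and never
  contribute evidence.
- **Zygosity windows**: in 50-kb windows, the percentage of confident
  heterozygous calls among confident calls (confident het + confident
  hom-alt + likely reference). Empty windows are missing, not 0%.

Segmentation first marks bins whose mean depth is below 0.7 × a
baseline (the 0.9 quantile of unflagged bin means — robust even when
the deletion covers most of the targeted region), bridges flagged bins,
and keeps candidate runs of at least 100 kb. A run is accepted as
hemizygous only with both evidence types: its depth ratio against the
median of unflagged bins outside the run must be < 0.7, **and** the
mean confident-het percentage over the zygosity windows fully contained
in it must be < 5%. The mean (rather than each window individually) is
used so that realistic platform artifact rates do not veto a true
deletion through one noisy window. The longest (then leftmost)
qualifying run wins.

The segment is then anchored to the LCR map: an endpoint within an LCR
or within ±10 kb of one takes that LCR's label, giving the classes AB,
AC, AD, BD. A deletion whose start is interstitial between A and B but
whose end anchors to B is labeled A+B; one anchored at A whose end
falls short of C (past B) is AC−; anything else atypical-other. Within
an accepted deletion, stretches of depth ≤ 1 of at least 10 kb are
reported as candidate nullisomy (homozygous loss) and screened rather
than silently absorbed.

## 3. Cohort catalog (`hemivar.catalog`)

Kept calls from all patients are pooled by (position, ref, alt). Each
entry records its carriers and the number of cohort deletions spanning
the position; cohort frequency is carriers / spanning deletions, so a
variant inside a rare deletion class is not diluted by patients who do
not even carry that DNA. A kept call outside its patient's typed
deletion is a hard error, not a warning.

Coding effects are computed by codon: the variant's CDS offset locates
its codon, the codon is rebuilt with the alternate base
(reverse-complemented for minus-strand genes) and translated
(synonymous / non-synonymous / stop-gain); insertions are frameshift
iff their inserted length is not a multiple of 3. A variant is **rare**
iff its population frequency is missing or ≤ 5% **and** its cohort
frequency is ≤ 5% (both inclusive). Printed percentages use half-up
rounding at the printed precision.

## 4. Per-gene burden (`hemivar.burden`)

A base is **sequenceable** unless more than 75% of samples (strict
inequality) had depth ≤ 1 there, or it lies in a segmental duplication.
For each gene × {exonic, coding, intronic} and each intergenic block,
the sequenceable length and the number of catalog variants on
sequenceable bases are tallied. Per compartment, variant count is
regressed on sequenceable length by ordinary least squares, and
externally Studentized residuals (leave-one-out error variance) beyond
±2 flag genes with more or fewer variants than their sequenceable
length predicts. Degenerate fits are handled explicitly: a numerically
perfect fit reports zero residuals, and leave-one-out variances that
collapse on very small point sets yield missing (never spurious)
flags. Mean conservation per gene over the same sequenceable bases is
reported alongside, ranked within compartment.

## 5. Platform clustering (`hemivar.clustering`)

For patients of one deletion class (default AD), each patient becomes a
pseudo-sequence over the class's catalog positions: V at kept
hemizygous variants, R at confident reference emissions, N otherwise.
Pairwise p-distances use pairwise deletion (sites where neither symbol
is N); patients with no comparable sites are dropped rather than
imputed. A UPGMA tree is built (size-weighted mean linkage, ties broken
by lexicographically smallest label pair) and a platform-segregation
purity score — the unweighted mean over the clusters of a k = 2 cut of
each cluster's majority-platform fraction — quantifies whether the tree
splits by capture platform. Purity near the null (assessed by label
permutation) means variation clusters by genotype, not by platform
batch effects.

## 6. Synthetic cohorts (`hemivar.simulate`)

The generator builds an 800-kb region with four LCRs, in-LCR segmental
duplications, 40 genes, a conservation track and a known-variant table,
plus a population variant pool whose density and allele-frequency
spectrum are set so that a hemizygous patient carries on the order of
5.8 × 10⁻⁴ variants per base. Patients draw a deletion class
(8/2/111/4/1/1 over 127 across AB/AC/AD/BD/A+B/AC−, remainder none),
Poisson depth (80× diploid, 0.5× inside the deletion), and per-variant
PL triples; heterozygous artifact calls arise inside deletions at a
per-platform rate (11.6% baseline, ~2.1× on the second platform).
Hard-to-capture blocks depress depth but are kept away from true
breakpoints so that truth intervals remain recoverable evidence, not
generator artifacts. Everything is keyed off
`numpy.random.SeedSequence`, and fixture output (VCF, depth tables,
BEDs, YAML manifest) is byte-identical for a fixed seed.

`simulate_burden_points` generates burden-regression point sets
directly (Poisson counts at cohort-scale density over random gene
lengths), optionally with one zero-density unit, for calibrating the
outlier rule's power and null flag rate without re-simulating full
cohorts.

## 7. Packaged reference tables (`hemivar.data`)

`cohort_counts.json` holds headline bookkeeping counts of a published
127-patient 22q11.2 deletion resequencing cohort (position counts
before/after filtering, annotation and coding breakdowns, deletion
class counts, platform sizes and artifact rates);
`cohort_gene_variants.tsv` the per-gene protein-altering variant tally
of that cohort. They are used as arithmetic worked examples (the
package's percentage and roll-up routines must reproduce the published
derived numbers exactly) and as defaults for simulator calibration —
not as outputs claimed to be recomputed from raw data.
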