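# hemivar

Cataloging hemizygous variation in microdeletion cohorts from targeted
resequencing data, modeled on the 22q11.2 deletion region.

## Background

Patients with a heterozygous microdeletion carry a single copy of every
base inside the deleted interval. Targeted resequencing of that interval
therefore reads out the surviving haplotype directly: every confident
non-reference call inside the deletion is hemizygous, with no second
allele to mask it. This makes deletion cohorts unusually clean material
for cataloging variation — but only after two problems are solved:

1. **Where exactly is each patient's deletion?** In the 22q11.2 region,
   deletions are mediated by four large low-copy repeats (LCR A–D), so
   most patients fall into one of the recurrent classes AB, AC, AD or
   BD, with occasional atypical events (a deletion starting between A
   and B, written A+B, or ending short of C, written AC−). The deletion
   boundary must be recovered per patient from read depth and
   heterozygosity before any call inside it can be interpreted.
2. **Which calls are trustworthy?** A heterozygous genotype call inside
   a hemizygous interval is physically impossible and marks either a
   capture/alignment artifact or a mis-mapped paralogous read; the rate
   of such artifact calls differs systematically between capture
   platforms. Calls must be filtered by their Phred-scaled genotype
   likelihoods (PL) before they enter a cohort catalog.

`hemivar` implements the full analysis: PL-based call classification and
filtering, depth/zygosity-based deletion typing against an LCR map,
cohort-level variant cataloging with coding-effect and rarity
annotation, per-gene burden regression with Studentized-residual outlier
detection, and a UPGMA clustering check for capture-platform batch
effects. A seeded synthetic-cohort generator with full ground truth
drives validation end to end; bookkeeping tables from a published
127-patient 22q11.2 cohort are packaged for worked-example arithmetic.

## Quickstart

```sh
$ hemivar demo --seed 1 --outdir demo_out
patients: 24  classes: {'AB': 3, 'AC-': 1, 'AD': 20}
hemizygous positions: 2320 -> 2107 after het removal
catalog size: 2108  rare: 987
platform purity: 0.763157894736842
artifacts in demo_out/
```

This simulates a 24-patient cohort and runs every stage, writing
`deletions.tsv`/`deletions.bed` (per-patient typed deletion with LCR
anchors and depth ratio), `catalog.tsv` (the cohort variant catalog),
`removals.tsv` (per-call filter ledger), `burden_points.tsv` and
`burden_fit_<compartment>.tsv` (burden regression inputs and
diagnostics), `conservation.tsv`, `gene_variant_matrix.tsv`,
`platform_tree.nwk` (UPGMA tree) and `report.json` (stage-by-stage
bookkeeping counts).

The other subcommands are `hemivar simulate` (fixtures only: per-patient
VCF + depth tracks + region BEDs + manifest), `hemivar run-all`
(full pipeline under a YAML config) and `hemivar report` (JSON report
only).

## Worked library example

```python
from hemivar.calls import PLTriple, classify_call, passes_hemizygous_keep
from hemivar.deletions import type_patient
from hemivar.simulate import CohortSpec, simulate_cohort

# A normalized PL triple (hom-ref, het, hom-alt). Hom-alt likelihood 0
# and hom-ref > 70 means: keep as a hemizygous variant.
pl = PLTriple(ref=112.0, het=88.0, alt=0.0)
print(classify_call(pl).value, passes_hemizygous_keep(pl))

# Simulate two patients (one AD deletion, one without a deletion) and
# type the first from depth + zygosity alone.
cohort = simulate_cohort(CohortSpec(seed=1, n_patients=2),
                         class_sequence=["AD", "none"])
p = cohort.patients[0]
dc = type_patient(p.patient_id, p.depth, p.calls, cohort.region)
print(dc.class_label, dc.interval.start, dc.interval.end, round(dc.depth_ratio, 3))
print(p.truth.deletion_class, p.truth.interval.start, p.truth.interval.end)
```

Output:

```
confident_hom_alt True
AD 70001 670000 0.495
AD 70037 670037
```

The recovered interval sits within one 100-bp coverage bin of the
simulated truth, and the in-deletion/out-of-deletion depth ratio is the
expected 0.5.

## Package layout

| Module | Contents |
| --- | --- |
| `hemivar.regions` | Genomic interval model, LCR map, gene models, segdup mask, conservation and known-variant tracks, BED/table I/O |
| `hemivar.calls` | PL triples, seven-way call classification, hemizygous keep rule, call-set filtering with a removal ledger |
| `hemivar.vcfio` | Per-patient VCF writing/reading (GT:PL) via pysam |
| `hemivar.deletions` | Coverage binning, zygosity windows, two-evidence segmentation, LCR anchoring into deletion classes, nullisomy screen |
| `hemivar.catalog` | Cohort catalog, coding-effect calls via codon translation, rare rule, half-up percentage arithmetic, per-gene variant matrix |
| `hemivar.burden` | Sequenceable-base mask, per-compartment variant counting, count~length OLS with externally Studentized residuals |
| `hemivar.clustering` | R/V/N pseudo-sequences, p-distance with pairwise deletion, UPGMA, platform-segregation purity, newick/PHYLIP output |
| `hemivar.simulate` | Seeded synthetic region + cohort generator with full truth records, text fixture writer |
| `hemivar.pipeline` / `hemivar.cli` | End-to-end orchestration, YAML config, artifact writer, `hemivar` CLI |
| `hemivar.data` | `cohort_counts.json` (published headline counts) and `cohort_gene_variants.tsv` (per-gene protein-altering tally) |

See `docs/methods.md` for the methods in detail.

## Reproduction

All results are deterministic given a seed.

```sh
pip install --no-build-isolation -e '.[test]'
python -m pytest -q tests/                 # full suite, ~3 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script writes one JSON object per metric,
`{"value": ..., "n": ...}`. Metrics `t1`–`t10` are seed-independent
worked-example arithmetic on the packaged cohort tables and must come
out exactly as:

| id | value | meaning |
| --- | --- | --- |
| t1 | 84 | % of post-filter hemizygous positions present in the known-variant annotation (9,990 / 11,913) |
| t2 | 57.8 | % of initial positions annotated (10,493 / 18,153) |
| t3 | 1.7 | % of post-filter positions in coding sequence (199 / 11,913) |
| t4 | 44 | % synonymous among coding positions (88 / 199) |
| t5 | 48 | % non-synonymous among coding positions (95 / 199) |
| t6 | 127 | deletion-class counts sum to the cohort size |
| t7 | 28 | genes with any protein-altering variant |
| t8 | 25 | genes with any rare protein-altering variant |
| t9 | 63 | rare non-synonymous variants |
| t10 | 95 | total non-synonymous variants |

The remaining metrics are seeded synthetic checks; for any seed the
expected outcomes are `class_recovery_pct` = 100.0 (n = 140, all seven
deletion classes, breakpoints within one 100-bp bin),
`studentized_max_abs_diff_vs_loo` ≤ 1e−9 against a leave-one-out brute
force, `intolerant_gene_flag_pct` ≥ 95, `upgma_exact_match_pct` = 100
against a brute-force reference, `pl_classification_consistent_pct` =
100 over 10⁵ random PL triples, and `platform_purity_within_null_ci` = 1
(no spurious platform segregation on a platform-neutral cohort).
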