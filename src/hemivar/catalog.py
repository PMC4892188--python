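"""Cohort-level catalog of unique hemizygous variant positions.

Aggregates each patient's kept hemizygous calls into one entry per unique
(position, alt allele), computes the cohort allele frequency against the
number of patients whose deletion spans the position (one allele each),
annotates functional category and coding effect, applies the rare-variant
rule (population AF <= 5% AND cohort frequency <= 5%), and produces the
summary tables: category/effect totals, percent previously annotated,
per-deletion-class per-patient means, and the gene x protein-altering
variant matrix with its roll-ups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .calls import CallRecord
from .deletions import DeletionCall
from .regions import GeneModel, RegionModel, functional_category

__all__ = [
    "CatalogEntry",
    "CatalogSummary",
    "build_catalog",
    "classify_coding_effect",
    "flag_rare",
    "summarize_catalog",
    "percentage",
    "round_half_up",
    "gene_variant_matrix",
    "matrix_rollups",
    "load_gene_variant_table",
]

CODING_EFFECTS = (
    "synonymous",
    "non_synonymous",
    "stop_gain",
    "frameshift_insertion",
    "other",
    "not_coding",
)

PROTEIN_ALTERING = ("stop_gain", "frameshift_insertion", "non_synonymous")


@dataclass
class CatalogEntry:
    position: int
    ref: str
    alt: str
    carriers: set[str]
    spanning: int
    population_freq: Optional[float]
    annotated: bool
    category: str
    gene: Optional[str] = None
    coding_effect: str = "not_coding"
    rare: bool = False

    @property
    def cohort_freq(self) -> float:
        return len(self.carriers) / self.spanning if self.spanning else float("nan")


def build_catalog(
    kept_calls: Mapping[str, Sequence[CallRecord]],
    deletion_calls: Mapping[str, DeletionCall],
    region: RegionModel,
) -> list[CatalogEntry]:
    """One entry per unique (position, alt) across all patients' kept calls.

    Every kept call must lie inside its patient's deletion; a call outside
    it means the hemizygous filter was skipped and is a hard error.
    """
    spans = {
        pid: dc.interval for pid, dc in deletion_calls.items() if dc.interval is not None
    }
    grouped: dict[tuple[int, str, str], set[str]] = {}
    for pid, calls in kept_calls.items():
        interval = spans.get(pid)
        for c in calls:
            if interval is None or not interval.contains(c.position):
                raise ValueError(
                    f"kept call for {pid} at {c.position} lies outside the "
                    "patient's deletion; run the hemizygous filter first"
                )
            grouped.setdefault((c.position, c.ref, c.alt), set()).add(pid)

    positions = sorted(grouped)
    entries = []
    for pos, ref, alt in positions:
        spanning = sum(1 for iv in spans.values() if iv.contains(pos))
        pop = (
            region.known_variants.frequency(pos, ref, alt)
            if region.known_variants
            else None
        )
        category = functional_category(pos, region.genes)
        gene = None
        if category != "intergenic":
            for g in region.genes:
                if g.position_category(pos) == category:
                    gene = g.name
                    break
        entries.append(
            CatalogEntry(
                position=pos,
                ref=ref,
                alt=alt,
                carriers=grouped[(pos, ref, alt)],
                spanning=spanning,
                population_freq=pop,
                annotated=pop is not None,
                category=category,
                gene=gene,
            )
        )
    return entries


def _coding_gene(pos: int, genes: Sequence[GeneModel]) -> Optional[GeneModel]:
    for g in genes:
        if g.position_category(pos) == "coding_exonic":
            return g
    return None


def classify_coding_effect(
    entry: CatalogEntry, genes: Sequence[GeneModel], region: RegionModel
) -> str:
    """Classify a coding variant's effect on the protein.

    SNVs are translated in the gene's frame: same amino acid is
    synonymous, a different non-stop amino acid non-synonymous, a stop
    codon a stop-gain. Insertions with inserted length not a multiple of
    3 are frameshift insertions; everything else (in-frame indels,
    unresolvable frames) is "other".
    """
    if entry.category != "coding_exonic":
        return "not_coding"
    gene = _coding_gene(entry.position, genes)
    if gene is None:
        warnings.warn(f"no coding frame at position {entry.position}")
        return "other"
    if len(entry.alt) > len(entry.ref):
        ins_len = len(entry.alt) - len(entry.ref)
        return "frameshift_insertion" if ins_len % 3 else "other"
    if len(entry.alt) != 1 or len(entry.ref) != 1:
        return "other"

    # CDS offset of the position in transcription order
    coding = gene.coding if gene.strand == "+" else list(reversed(gene.coding))
    offset = 0
    found = False
    for civ in coding:
        if civ.contains(entry.position):
            if gene.strand == "+":
                offset += entry.position - civ.start
            else:
                offset += civ.end - entry.position
            found = True
            break
        offset += civ.length
    if not found:
        warnings.warn(f"position {entry.position} outside coding frame of {gene.name}")
        return "other"

    cds_len = sum(civ.length for civ in gene.coding)
    codon_idx = offset // 3
    if (codon_idx + 1) * 3 > cds_len:
        warnings.warn(f"incomplete terminal codon at {entry.position} in {gene.name}")
        return "other"

    # collect the three genomic positions of this codon, transcription order
    cds_positions: list[int] = []
    for civ in coding:
        rng = (
            range(civ.start, civ.end + 1)
            if gene.strand == "+"
            else range(civ.end, civ.start - 1, -1)
        )
        cds_positions.extend(rng)
    codon_pos = cds_positions[codon_idx * 3 : codon_idx * 3 + 3]

    def codon_seq(alt_base: Optional[str]) -> str:
        bases = []
        for p in codon_pos:
            b = entry.alt if (alt_base and p == entry.position) else region.base(p)
            if gene.strand == "-":
                b = str(Seq(b).complement())
            bases.append(b)
        return "".join(bases)

    aa_ref = str(Seq(codon_seq(None)).translate())
    aa_alt = str(Seq(codon_seq(entry.alt)).translate())
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gain"
    return "non_synonymous"


def flag_rare(entry: CatalogEntry, threshold: float = 0.05) -> bool:
    """Rare iff population AF (missing counts as rare) and cohort
    frequency are both at or below the threshold (inclusive)."""
    pop_ok = entry.population_freq is None or entry.population_freq <= threshold
    return pop_ok and entry.cohort_freq <= threshold


def annotate_catalog(
    catalog: list[CatalogEntry],
    region: RegionModel,
    rare_threshold: float = 0.05,
) -> list[CatalogEntry]:
    """Fill coding effects and rare flags in place; returns the catalog."""
    for e in catalog:
        e.coding_effect = classify_coding_effect(e, region.genes, region)
        e.rare = flag_rare(e, rare_threshold)
    return catalog


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero at the given decimals (report style)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(n: float, d: float, decimals: Optional[int] = None) -> Optional[float]:
    """100*n/d, optionally half-up rounded; None on a zero denominator."""
    if d == 0:
        return None
    p = 100.0 * n / d
    return p if decimals is None else round_half_up(p, decimals)


@dataclass
class CatalogSummary:
    total: int
    by_category: dict[str, int]
    by_coding_effect: dict[str, int]
    n_annotated: int
    pct_annotated: Optional[float]
    rare_total: int
    rare_by_effect: dict[str, int]
    mean_variants_per_patient_by_class: dict[str, float] = field(default_factory=dict)


def summarize_catalog(
    catalog: Sequence[CatalogEntry],
    deletion_calls: Optional[Mapping[str, DeletionCall]] = None,
) -> CatalogSummary:
    """Totals, annotation percentage and per-deletion-class means."""
    by_cat = {c: 0 for c in ("coding_exonic", "noncoding_exonic", "intronic", "intergenic")}
    by_eff = {e: 0 for e in CODING_EFFECTS if e != "not_coding"}
    rare_by_eff = {e: 0 for e in by_eff}
    n_annot = 0
    rare_total = 0
    for e in catalog:
        by_cat[e.category] += 1
        if e.coding_effect != "not_coding":
            by_eff[e.coding_effect] += 1
            if e.rare:
                rare_by_eff[e.coding_effect] += 1
        if e.annotated:
            n_annot += 1
        if e.rare:
            rare_total += 1

    means: dict[str, float] = {}
    if deletion_calls:
        per_class_counts: dict[str, list[int]] = {}
        for pid, dc in deletion_calls.items():
            if dc.interval is None:
                continue
            n = sum(1 for e in catalog if pid in e.carriers)
            per_class_counts.setdefault(dc.class_label, []).append(n)
        means = {
            cls: float(np.mean(v)) for cls, v in sorted(per_class_counts.items())
        }

    return CatalogSummary(
        total=len(catalog),
        by_category=by_cat,
        by_coding_effect=by_eff,
        n_annotated=n_annot,
        pct_annotated=percentage(n_annot, len(catalog)),
        rare_total=rare_total,
        rare_by_effect=rare_by_eff,
        mean_variants_per_patient_by_class=means,
    )


# ---------------------------------------------------------------------------
# Gene x protein-altering-variant matrix
# ---------------------------------------------------------------------------

_MATRIX_COLS = [
    "stop_gain_total",
    "stop_gain_rare",
    "frameshift_insertion_total",
    "frameshift_insertion_rare",
    "non_synonymous_total",
    "non_synonymous_rare",
]


def gene_variant_matrix(
    catalog: Sequence[CatalogEntry], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Per-gene counts of protein-altering variants, total and rare.

    One row per gene with at least one protein-altering entry; counts are
    unique (position, alt) catalog entries.
    """
    rows: dict[str, dict[str, int]] = {}
    for e in catalog:
        if e.coding_effect not in PROTEIN_ALTERING or e.gene is None:
            continue
        row = rows.setdefault(e.gene, {c: 0 for c in _MATRIX_COLS})
        row[f"{e.coding_effect}_total"] += 1
        if e.rare:
            row[f"{e.coding_effect}_rare"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index", columns=_MATRIX_COLS)
    df.index.name = "gene"
    return df.sort_index()


def matrix_rollups(df: pd.DataFrame) -> dict[str, int]:
    """Column sums plus the two gene-level roll-ups.

    ``genes_protein_altering`` counts genes with any protein-altering
    variant; ``genes_rare_protein_altering`` those with any rare one.
    """
    totals = {c: int(df[c].sum()) for c in _MATRIX_COLS} if len(df) else {
        c: 0 for c in _MATRIX_COLS
    }
    any_total = (
        (df[[f"{e}_total" for e in PROTEIN_ALTERING]].sum(axis=1) > 0)
        if len(df)
        else pd.Series(dtype=bool)
    )
    any_rare = (
        (df[[f"{e}_rare" for e in PROTEIN_ALTERING]].sum(axis=1) > 0)
        if len(df)
        else pd.Series(dtype=bool)
    )
    totals["genes_protein_altering"] = int(any_total.sum())
    totals["genes_rare_protein_altering"] = int(any_rare.sum())
    return totals


def load_gene_variant_table(path: str | Path) -> pd.DataFrame:
    """Load a per-gene protein-altering variant tally (TSV).

    Expected columns: gene, then for each of stop_gain,
    frameshift_insertion and non_synonymous a ``<effect>_total`` and
    ``<effect>_rare`` pair. Genes with all-zero rows are dropped so the
    result matches the shape :func:`gene_variant_matrix` produces.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index("gene")[_MATRIX_COLS].astype(int)
    nonzero = df[[f"{e}_total" for e in PROTEIN_ALTERING]].sum(axis=1) > 0
    return df[nonzero].sort_index()
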