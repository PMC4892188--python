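"""End-to-end orchestration of the hemizygous-variant analysis.

Runs classification -> deletion typing -> cohort catalog -> per-gene
burden -> platform clustering on a synthetic cohort (or on pre-simulated
cohort objects), collecting stage-by-stage bookkeeping counts into a
deterministic JSON run report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import catalog as catalog_mod
from . import clustering as clustering_mod
from .calls import CallRecord, RemovalReason, filter_call_set
from .deletions import DeletionCall, SegmentationParams, type_patient
from .regions import write_bed
from .simulate import Cohort, CohortSpec, simulate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_artifacts"]


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, with study defaults.

    ``pl_threshold`` (Phred units) drives call classification and the
    hemizygous keep rule; ``bin_size``/``window`` the coverage and
    zygosity grids; ``depth_ratio_max``/``het_max``/``min_len`` the
    deletion segmentation; ``rare_threshold`` the rare-variant rule;
    ``seq_max_low_reads``/``seq_min_sample_fraction`` the sequenceable
    mask; ``residual_cutoff`` the burden outlier rule.
    """

    seed: int = 0
    n_patients: int = 127
    pl_threshold: float = 70.0
    bin_size: int = 100
    window: int = 50_000
    depth_ratio_max: float = 0.7
    het_max: float = 5.0
    min_len: int = 100_000
    rare_threshold: float = 0.05
    seq_max_low_reads: int = 1
    seq_min_sample_fraction: float = 0.75
    residual_cutoff: float = 2.0
    cluster_class: str = "AD"
    drop_uncomparable: bool = True
    outdir: Optional[str] = None
    cohort: dict = field(default_factory=dict)  # overrides for CohortSpec

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(seed=self.seed, n_patients=self.n_patients, **self.cohort)

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            depth_ratio_max=self.depth_ratio_max,
            het_max=self.het_max,
            min_len=self.min_len,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: Cohort
    deletion_calls: dict[str, DeletionCall]
    catalog: list
    summary: catalog_mod.CatalogSummary
    burden_points: pd.DataFrame
    burden_fits: dict[str, burden_mod.RegressionResult]
    conservation: pd.DataFrame
    tree: Optional[clustering_mod.ClusterNode]
    purity: Optional[float]
    removal_ledger: pd.DataFrame
    report: dict


def run_pipeline(
    config: PipelineConfig, cohort: Optional[Cohort] = None
) -> PipelineResult:
    """Execute all stages; deterministic for a fixed config/seed."""
    cohort = cohort or simulate_cohort(config.cohort_spec())
    region = cohort.region
    params = config.segmentation_params()

    # ---- stage 1+2: per-patient classification filters and deletion typing
    deletion_calls: dict[str, DeletionCall] = {}
    kept_hemizygous: dict[str, list[CallRecord]] = {}
    ledger_rows = []
    n_initial_calls = 0
    removed_by_reason = {r.value: 0 for r in RemovalReason}
    pre_positions: set[int] = set()
    post_positions: set[int] = set()

    for p in cohort.patients:
        n_initial_calls += len(p.calls)
        dc = type_patient(
            p.patient_id,
            p.depth,
            p.calls,
            region,
            params,
            config.bin_size,
            config.window,
            config.pl_threshold,
        )
        deletion_calls[p.patient_id] = dc
        result = filter_call_set(
            p.calls, region.segdups, dc.interval, config.pl_threshold
        )
        for rec, reason in result.removed:
            removed_by_reason[reason.value] += 1
            ledger_rows.append(
                {"patient": p.patient_id, "position": rec.position, "reason": reason.value}
            )
        if dc.interval is not None:
            inside = [c for c in result.kept if dc.interval.contains(c.position)]
            kept_hemizygous[p.patient_id] = inside
            post_positions.update(c.position for c in inside)
            # pre-het-removal bookkeeping: variant-class calls inside the
            # deletion that survived the segdup/reference/indeterminable pass
            pre_positions.update(
                c.position for c in inside
            )
            pre_positions.update(
                rec.position
                for rec, reason in result.removed
                if reason is RemovalReason.FAILS_HEMIZYGOUS_KEEP
            )
        else:
            kept_hemizygous[p.patient_id] = []

    # ---- stage 3: cohort catalog
    cat = catalog_mod.build_catalog(kept_hemizygous, deletion_calls, region)
    catalog_mod.annotate_catalog(cat, region, config.rare_threshold)
    summary = catalog_mod.summarize_catalog(cat, deletion_calls)
    matrix = catalog_mod.gene_variant_matrix(cat, region.genes)
    rollups = catalog_mod.matrix_rollups(matrix)

    # annotation percentages before and after heterozygous removal
    known = region.known_variants
    def _pct_annot(positions: set[int]) -> Optional[float]:
        if not positions or known is None:
            return None
        annotated_pos = {pos for (pos, _, _) in known.records}
        return catalog_mod.percentage(
            len(positions & annotated_pos), len(positions), 1
        )

    # ---- stage 4: burden and conservation
    seq_mask = burden_mod.sequenceable_mask(
        (p.depth for p in cohort.patients),
        region.span,
        region.segdups,
        config.seq_max_low_reads,
        config.seq_min_sample_fraction,
    )
    points = burden_mod.count_burden(cat, region, seq_mask)
    fits = {}
    for comp in burden_mod.COMPARTMENTS:
        sub = points[points["compartment"] == comp]
        fits[comp] = burden_mod.fit_length_model(sub, config.residual_cutoff)
    conservation = burden_mod.mean_conservation(region, seq_mask)

    # ---- stage 5: platform clustering within one deletion class
    cluster_ids = [
        pid
        for pid, dc in deletion_calls.items()
        if dc.class_label == config.cluster_class
    ]
    tree, purity = None, None
    if len(cluster_ids) >= 3:
        positions = sorted(
            {
                e.position
                for e in cat
                if any(pid in e.carriers for pid in cluster_ids)
            }
        )
        call_sets = {
            p.patient_id: p.calls
            for p in cohort.patients
            if p.patient_id in cluster_ids
        }
        kept_pos = {
            pid: {c.position for c in kept_hemizygous[pid]} for pid in cluster_ids
        }
        platforms = {p.patient_id: p.platform for p in cohort.patients}
        seqs = clustering_mod.build_pseudosequences(
            call_sets, kept_pos, positions, platforms, config.pl_threshold
        )
        dmat = clustering_mod.distance_matrix(seqs)
        if dmat.has_missing and config.drop_uncomparable:
            ok = [
                i
                for i in range(len(dmat.labels))
                if not np.isnan(np.delete(dmat.d[i], i)).any()
            ]
            seqs = [seqs[i] for i in ok]
            dmat = clustering_mod.distance_matrix(seqs)
        if len(dmat.labels) >= 3 and not dmat.has_missing:
            tree = clustering_mod.upgma(dmat)
            cluster_platforms = {s.patient: s.platform for s in seqs}
            if len(set(cluster_platforms.values())) >= 2:
                purity = clustering_mod.platform_segregation_score(
                    tree, cluster_platforms
                )

    ledger = pd.DataFrame(ledger_rows, columns=["patient", "position", "reason"])
    class_counts: dict[str, int] = {}
    for dc in deletion_calls.values():
        class_counts[dc.class_label] = class_counts.get(dc.class_label, 0) + 1

    report = {
        "seed": config.seed,
        "n_patients": len(cohort.patients),
        "stages": {
            "classification": "ok",
            "deletion_typing": "ok",
            "catalog": "ok",
            "burden": "ok",
            "clustering": "ok" if tree is not None else "skipped",
        },
        "initial_calls": n_initial_calls,
        "removed_by_reason": removed_by_reason,
        "kept_calls": n_initial_calls - sum(removed_by_reason.values()),
        "deletion_class_counts": dict(sorted(class_counts.items())),
        "hemizygous_positions_pre_het_removal": len(pre_positions),
        "hemizygous_positions_post_het_removal": len(post_positions),
        "pct_annotated_pre": _pct_annot(pre_positions),
        "pct_annotated_post": _pct_annot(post_positions),
        "catalog_size": summary.total,
        "catalog_by_category": summary.by_category,
        "catalog_by_coding_effect": summary.by_coding_effect,
        "rare_total": summary.rare_total,
        "rare_by_effect": summary.rare_by_effect,
        "mean_variants_per_patient_by_class": summary.mean_variants_per_patient_by_class,
        "gene_matrix_rollups": rollups,
        "burden_outliers": {
            comp: fit.outliers["unit"].tolist() if fit.ok else []
            for comp, fit in fits.items()
        },
        "platform_purity": purity,
    }

    result = PipelineResult(
        config=config,
        cohort=cohort,
        deletion_calls=deletion_calls,
        catalog=cat,
        summary=summary,
        burden_points=points,
        burden_fits=fits,
        conservation=conservation,
        tree=tree,
        purity=purity,
        removal_ledger=ledger,
        report=report,
    )
    if config.outdir:
        write_artifacts(result, config.outdir)
    return result


def write_artifacts(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    region = result.cohort.region

    rows = []
    deletion_ivs, deletion_names = [], []
    for pid, dc in sorted(result.deletion_calls.items()):
        rows.append(
            {
                "patient": pid,
                "class": dc.class_label,
                "start": dc.interval.start if dc.interval else "",
                "end": dc.interval.end if dc.interval else "",
                "start_anchor": dc.start_anchor[0],
                "start_offset": dc.start_anchor[1],
                "end_anchor": dc.end_anchor[0],
                "end_offset": dc.end_anchor[1],
                "depth_ratio": dc.depth_ratio,
                "n_nullisomy": len(dc.nullisomy),
            }
        )
        if dc.interval is not None:
            deletion_ivs.append(dc.interval)
            deletion_names.append(pid)
    pd.DataFrame(rows).to_csv(outdir / "deletions.tsv", sep="\t", index=False)
    write_bed(outdir / "deletions.bed", deletion_ivs, names=deletion_names)

    cat_rows = [
        {
            "position": e.position,
            "ref": e.ref,
            "alt": e.alt,
            "n_carriers": len(e.carriers),
            "spanning": e.spanning,
            "cohort_freq": round(e.cohort_freq, 6),
            "population_freq": "" if e.population_freq is None else e.population_freq,
            "annotated": e.annotated,
            "category": e.category,
            "gene": e.gene or "",
            "coding_effect": e.coding_effect,
            "rare": e.rare,
        }
        for e in result.catalog
    ]
    pd.DataFrame(cat_rows).to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    result.removal_ledger.to_csv(outdir / "removals.tsv", sep="\t", index=False)
    result.burden_points.to_csv(outdir / "burden_points.tsv", sep="\t", index=False)
    for comp, fit in result.burden_fits.items():
        if fit.ok:
            fit.table.to_csv(
                outdir / f"burden_fit_{comp}.tsv", sep="\t", index=False
            )
    result.conservation.to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    matrix = catalog_mod.gene_variant_matrix(result.catalog, region.genes)
    matrix.to_csv(outdir / "gene_variant_matrix.tsv", sep="\t")
    if result.tree is not None:
        (outdir / "platform_tree.nwk").write_text(
            clustering_mod.to_newick(result.tree) + "\n"
        )
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
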