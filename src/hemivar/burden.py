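"""Per-gene variant burden: sequenceable masking, counting, regression.

The expected number of variants per gene scales with how much of the gene
could actually be sequenced. Bases are "sequenceable" unless they had 0
or 1 reads in more than 75% of samples or overlap a segmental
duplication. Catalog variants are then counted per gene and compartment
(exonic, coding, intronic) and per intergenic block, an ordinary
least-squares line of count on sequenceable length is fitted per
compartment, and genes with externally Studentized residuals beyond +/-2
are flagged as carrying more or fewer variants than expected. Mean
conservation per gene is computed over the same sequenceable bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .catalog import CatalogEntry
from .regions import ConservationTrack, GeneModel, GenomeInterval, RegionModel, SegDupMask

__all__ = [
    "SequenceableMask",
    "sequenceable_mask",
    "count_burden",
    "fit_length_model",
    "RegressionResult",
    "mean_conservation",
]

COMPARTMENTS = ("exonic", "coding", "intronic", "intergenic")


@dataclass
class SequenceableMask:
    """Per-position sequenceability over the region span."""

    region: GenomeInterval
    sequenceable: np.ndarray  # bool, aligned to region.start
    max_low_reads: int = 1
    min_sample_fraction: float = 0.75

    def is_sequenceable(self, pos: int) -> bool:
        return bool(self.sequenceable[pos - self.region.start])

    def count_in(self, interval: GenomeInterval) -> int:
        lo = max(interval.start, self.region.start) - self.region.start
        hi = min(interval.end, self.region.end) - self.region.start + 1
        return int(self.sequenceable[lo:hi].sum()) if hi > lo else 0


def sequenceable_mask(
    depth_tracks: Iterable[np.ndarray],
    region: GenomeInterval,
    segdups: SegDupMask,
    max_low_reads: int = 1,
    min_sample_fraction: float = 0.75,
) -> SequenceableMask:
    """Mark each base sequenceable or not across the cohort.

    A base is non-sequenceable iff the fraction of samples with depth
    <= ``max_low_reads`` strictly exceeds ``min_sample_fraction``, or the
    base lies in a segmental duplication. The boundary is strict: exactly
    75% of samples at low depth still counts as sequenceable.
    """
    L = region.length
    low_counts = np.zeros(L, dtype=np.int64)
    n_samples = 0
    for track in depth_tracks:
        n_samples += 1
        t = np.zeros(L, dtype=np.int64)
        m = min(len(track), L)
        t[:m] = track[:m]
        low_counts += t <= max_low_reads
    if n_samples == 0:
        raise ValueError("at least one depth track is required")
    seq = (low_counts / n_samples) <= min_sample_fraction
    for iv in segdups.intervals:
        lo = max(iv.start, region.start) - region.start
        hi = min(iv.end, region.end) - region.start + 1
        if hi > lo:
            seq[lo:hi] = False
    return SequenceableMask(region, seq, max_low_reads, min_sample_fraction)


def _gene_compartment_intervals(
    gene: GeneModel, compartment: str
) -> list[GenomeInterval]:
    if compartment == "exonic":
        return gene.exons
    if compartment == "coding":
        return gene.coding
    if compartment == "intronic":
        introns = []
        for a, b in zip(gene.exons, gene.exons[1:]):
            if b.start > a.end + 1:
                introns.append(GenomeInterval(a.contig, a.end + 1, b.start - 1))
        return introns
    raise ValueError(compartment)


def count_burden(
    catalog: Sequence[CatalogEntry],
    region: RegionModel,
    mask: SequenceableMask,
) -> pd.DataFrame:
    """Sequenceable length and variant count per analysis unit.

    Units are gene x {exonic, coding, intronic} plus each intergenic
    block. Only catalog positions on sequenceable bases are counted, so a
    variant at a masked base contributes to neither count nor length.
    """
    positions = np.array(sorted({e.position for e in catalog}), dtype=int)

    def count_in(ivs: list[GenomeInterval]) -> int:
        total = 0
        for iv in ivs:
            lo = np.searchsorted(positions, iv.start, "left")
            hi = np.searchsorted(positions, iv.end, "right")
            total += sum(1 for p in positions[lo:hi] if mask.is_sequenceable(int(p)))
        return total

    rows = []
    for gene in region.genes:
        for comp in ("exonic", "coding", "intronic"):
            ivs = _gene_compartment_intervals(gene, comp)
            rows.append(
                {
                    "unit": gene.name,
                    "compartment": comp,
                    "sequenceable_length": sum(mask.count_in(iv) for iv in ivs),
                    "variant_count": count_in(ivs),
                }
            )
    for i, block in enumerate(region.intergenic_blocks()):
        rows.append(
            {
                "unit": f"intergenic_{i:03d}",
                "compartment": "intergenic",
                "sequenceable_length": mask.count_in(block),
                "variant_count": count_in([block]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    table: pd.DataFrame  # unit, length, count, residual, leverage, studentized, outlier, direction
    ok: bool = True
    message: str = ""

    @property
    def outliers(self) -> pd.DataFrame:
        return self.table[self.table["outlier"]]


def fit_length_model(
    points: pd.DataFrame,
    residual_cutoff: float = 2.0,
    external: bool = True,
) -> RegressionResult:
    """OLS of variant count on sequenceable length with outlier flags.

    Residuals are externally Studentized by default (leave-one-out error
    variance, the R ``rstudent`` diagnostic); ``external=False`` switches
    to internal studentization. Points beyond +/-``residual_cutoff`` are
    flagged with a direction: "fewer" (negative residual) or "more".
    Fewer than 3 points or zero length variance yields an error result.
    """
    df = points.reset_index(drop=True)
    x = df["sequenceable_length"].to_numpy(dtype=float)
    y = df["variant_count"].to_numpy(dtype=float)
    if len(df) < 3 or np.allclose(x.var(), 0):
        return RegressionResult(
            float("nan"), float("nan"), pd.DataFrame(), ok=False,
            message="need >= 3 points with varying lengths",
        )
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    if np.sqrt(fit.mse_resid) < 1e-10 * max(1.0, float(np.abs(y).mean())):
        # perfect fit: studentization is 0/0, define residuals as zero
        stud = np.zeros(len(y))
        infl = OLSInfluence(fit)
    else:
        infl = OLSInfluence(fit)
        with np.errstate(divide="ignore", invalid="ignore"):
            stud = (
                infl.resid_studentized_external
                if external
                else infl.resid_studentized_internal
            )
        # leave-one-out variance can be degenerate (0 df or leverage 1)
        # for very small point sets; such residuals are unusable
        stud = np.where(np.isfinite(stud), stud, np.nan)
    out = df.copy()
    out["residual"] = fit.resid
    out["leverage"] = infl.hat_matrix_diag
    out["studentized"] = stud
    with np.errstate(invalid="ignore"):
        out["outlier"] = np.abs(stud) > residual_cutoff
    out["direction"] = np.where(stud < 0, "fewer", "more")
    out.loc[~out["outlier"], "direction"] = ""
    return RegressionResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]), table=out
    )


def mean_conservation(
    region: RegionModel,
    mask: SequenceableMask,
    track: Optional[ConservationTrack] = None,
) -> pd.DataFrame:
    """Mean conservation score per gene over sequenceable exonic and
    coding bases, ranked descending within each compartment."""
    track = track or region.conservation
    if track is None:
        raise ValueError("no conservation track available")
    rows = []
    for gene in region.genes:
        for comp in ("exonic", "coding"):
            ivs = _gene_compartment_intervals(gene, comp)
            vals = []
            for iv in ivs:
                for pos in range(iv.start, iv.end + 1):
                    if mask.is_sequenceable(pos):
                        vals.append(track.score(pos))
            rows.append(
                {
                    "gene": gene.name,
                    "compartment": comp,
                    "mean_score": float(np.mean(vals)) if vals else np.nan,
                    "n_bases": len(vals),
                }
            )
    df = pd.DataFrame(rows)
    df["rank"] = df.groupby("compartment")["mean_score"].rank(
        ascending=False, method="min"
    )
    return df.sort_values(["compartment", "rank"]).reset_index(drop=True)
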