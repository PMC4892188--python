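"""Deletion typing from binned coverage and windowed zygosity.

A hemizygous deletion shows up as a long run of ~half-depth coverage bins
together with depletion of heterozygous calls (only one allele remains).
This module bins per-base depth into 100-bp bins, summarizes call classes
in 50-kb windows, segments the hemizygous interval with an explicit
two-evidence rule, anchors its endpoints to the LCR map to assign the
deletion class (AB/AC/AD/BD, the atypical A+B and AC- patterns, or
atypical-other), and screens the deleted interval for nullisomy
(near-zero residual depth on the remaining allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calls import CallClass, CallRecord, classify_call
from .regions import GenomeInterval, LCRMap, RegionModel, SegDupMask

__all__ = [
    "CoverageBins",
    "ZygosityWindows",
    "SegmentationParams",
    "DeletionCall",
    "bin_coverage",
    "zygosity_windows",
    "segment_hemizygous",
    "assign_deletion_class",
    "detect_nullisomy",
]


@dataclass
class CoverageBins:
    """Mean depth per fixed-size bin tiling the region."""

    bin_size: int
    starts: np.ndarray  # 1-based start position of each bin
    means: np.ndarray
    flagged: np.ndarray  # True where the bin overlaps a segdup
    region: GenomeInterval

    def bin_end(self, i: int) -> int:
        return min(int(self.starts[i]) + self.bin_size - 1, self.region.end)


@dataclass
class ZygosityWindows:
    """Call-class composition per fixed-size window tiling the region.

    ``pct_het_confident`` is the percentage of confident heterozygous
    calls among confident genotype calls of any kind (confident het,
    confident hom-alt, and reference calls); NaN where a window holds no
    such calls.
    """

    window_size: int
    starts: np.ndarray
    class_counts: dict[CallClass, np.ndarray]
    pct_by_class: dict[CallClass, np.ndarray]  # among classified calls; NaN if empty
    pct_het_confident: np.ndarray
    region: GenomeInterval


@dataclass
class SegmentationParams:
    depth_ratio_max: float = 0.7
    het_max: float = 5.0  # percent
    min_len: int = 100_000
    null_depth_max: float = 1.0
    null_min_len: int = 10_000
    # quantile of unflagged bin means taken as the diploid baseline; a high
    # quantile is needed because the deletion itself can cover most of the
    # captured region (a full-length deletion spans ~3/4 of it)
    baseline_quantile: float = 0.9


@dataclass
class DeletionCall:
    patient: str
    interval: Optional[GenomeInterval]
    class_label: str  # AB/AC/AD/BD/A+B/AC-/atypical-other/none
    start_anchor: tuple[str, int] = ("", 0)  # (LCR name or "interstitial", offset bp)
    end_anchor: tuple[str, int] = ("", 0)
    depth_ratio: float = float("nan")
    nullisomy: list[GenomeInterval] = field(default_factory=list)


def bin_coverage(
    depth: np.ndarray,
    region: GenomeInterval,
    mask: SegDupMask,
    bin_size: int = 100,
) -> CoverageBins:
    """Average per-base depth into fixed bins; flag bins overlapping segdups.

    ``depth`` must be aligned to ``region`` (index 0 = region.start);
    positions past the end of the array read as depth 0.
    """
    L = region.length
    full = np.zeros(L, dtype=float)
    n = min(len(depth), L)
    full[:n] = depth[:n]
    n_bins = (L + bin_size - 1) // bin_size
    starts = region.start + bin_size * np.arange(n_bins)
    means = np.array(
        [full[i * bin_size : (i + 1) * bin_size].mean() for i in range(n_bins)]
    )
    flagged = np.zeros(n_bins, dtype=bool)
    for iv in mask.intervals:
        lo = max((iv.start - region.start) // bin_size, 0)
        hi = min((iv.end - region.start) // bin_size, n_bins - 1)
        if hi >= lo:
            flagged[lo : hi + 1] = True
    return CoverageBins(bin_size, starts, means, flagged, region)


_CONFIDENT_GT = (
    CallClass.CONFIDENT_HET,
    CallClass.CONFIDENT_HOM_ALT,
    CallClass.LIKELY_REFERENCE,
)


def zygosity_windows(
    calls: Sequence[CallRecord],
    region: GenomeInterval,
    window: int = 50_000,
    threshold: float = 70.0,
) -> ZygosityWindows:
    """Tally call classes per window and compute class percentages.

    Percentages are among classified (non-``unclassified``) calls; empty
    windows report NaN rather than 0 so downstream consumers can treat
    them as missing.
    """
    n_win = (region.length + window - 1) // window
    starts = region.start + window * np.arange(n_win)
    counts = {cls: np.zeros(n_win, dtype=int) for cls in CallClass}
    for c in calls:
        w = (c.position - region.start) // window
        if 0 <= w < n_win:
            counts[classify_call(c.pl, threshold)][w] += 1

    classified_total = sum(
        counts[cls] for cls in CallClass if cls is not CallClass.UNCLASSIFIED
    )
    pct = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(classified_total > 0, classified_total, np.nan)
        for cls in CallClass:
            pct[cls] = 100.0 * counts[cls] / denom
        conf_total = sum(counts[cls] for cls in _CONFIDENT_GT)
        conf_denom = np.where(conf_total > 0, conf_total, np.nan)
        pct_het = 100.0 * counts[CallClass.CONFIDENT_HET] / conf_denom
    return ZygosityWindows(window, starts, counts, pct, pct_het, region)


def _candidate_runs(bins: CoverageBins, low: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of low unflagged bins; flagged bins bridge, not break.

    Returns (first_bin, last_bin) index pairs where the ends are low
    unflagged bins.
    """
    unflagged = ~bins.flagged
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(low)
    while i < n:
        if unflagged[i] and low[i]:
            j = i
            last_low = i
            while j + 1 < n and (bins.flagged[j + 1] or low[j + 1]):
                j += 1
                if not bins.flagged[j]:
                    last_low = j
            runs.append((i, last_low))
            i = j + 1
        else:
            i += 1
    return runs


def segment_hemizygous(
    bins: CoverageBins,
    zyg: Optional[ZygosityWindows],
    params: SegmentationParams = SegmentationParams(),
) -> Optional[GenomeInterval]:
    """Locate the hemizygous deletion, if any.

    Candidate bins are those whose depth falls below ``depth_ratio_max``
    times the diploid baseline (the ``baseline_quantile`` of unflagged
    bin means — a high quantile, since the deletion itself may cover most
    of the captured region); a candidate run must additionally have mean
    depth below ``depth_ratio_max`` times the median of unflagged bins
    outside the run. Segdup-flagged bins inside the run are ignored
    (their contents never influence the result). The run must span at
    least ``min_len`` bp and the mean percent-heterozygous across zygosity
    windows fully contained in it must stay below ``het_max`` (windows
    with no confident calls pass). Among qualifying runs the longest wins, ties
    to the leftmost. Returns None when no run qualifies — including the
    degenerate case of uniformly reduced depth, which offers no diploid
    baseline.
    """
    unflagged = ~bins.flagged
    if not unflagged.any():
        return None
    baseline = float(np.quantile(bins.means[unflagged], params.baseline_quantile))
    if baseline <= 0:
        return None
    low = unflagged & (bins.means < params.depth_ratio_max * baseline)

    qualifying: list[tuple[int, GenomeInterval]] = []
    for first, last in _candidate_runs(bins, low):
        interval = GenomeInterval(
            bins.region.contig, int(bins.starts[first]), bins.bin_end(last)
        )
        if interval.length < params.min_len:
            continue
        in_run = np.zeros(len(bins.means), dtype=bool)
        in_run[first : last + 1] = True
        outside = unflagged & ~in_run
        if not outside.any():
            continue
        baseline = float(np.median(bins.means[outside]))
        if baseline <= 0:
            continue
        run_mean = float(np.mean(bins.means[in_run & unflagged]))
        if run_mean / baseline >= params.depth_ratio_max:
            continue
        if zyg is not None and not _het_depleted(zyg, interval, params.het_max):
            continue
        qualifying.append((interval.length, interval))
    if not qualifying:
        return None
    qualifying.sort(key=lambda li: (-li[0], li[1].start))
    return qualifying[0][1]


def _het_depleted(zyg: ZygosityWindows, interval: GenomeInterval, het_max: float) -> bool:
    ends = zyg.starts + zyg.window_size - 1
    contained = (zyg.starts >= interval.start) & (ends <= interval.end)
    if not contained.any():
        # short run: fall back to windows overlapping the run
        contained = (zyg.starts <= interval.end) & (ends >= interval.start)
    vals = zyg.pct_het_confident[contained]
    vals = vals[~np.isnan(vals)]
    # average across windows: robust to single-window binomial noise
    return bool(len(vals) == 0 or float(np.mean(vals)) < het_max)


def _anchor(pos: int, lcr_map: LCRMap) -> tuple[str, int]:
    """Anchor a breakpoint to an LCR within tolerance, else interstitial.

    The offset is signed distance to the (nearest edge of the) nearest
    LCR; 0 when inside the LCR proper.
    """
    tol = lcr_map.breakpoint_tolerance_bp
    best: Optional[tuple[int, str]] = None
    for name, iv in lcr_map.lcrs:
        if iv.start - tol <= pos <= iv.end + tol:
            dist = 0 if iv.contains(pos) else min(abs(pos - iv.start), abs(pos - iv.end))
            if best is None or dist < best[0]:
                best = (dist, name)
    if best is not None:
        return best[1], 0
    # interstitial: signed offset to nearest LCR edge
    nearest: Optional[tuple[int, int]] = None  # (abs distance, signed offset)
    for _, iv in lcr_map.lcrs:
        for edge in (iv.start, iv.end):
            off = pos - edge
            if nearest is None or abs(off) < nearest[0]:
                nearest = (abs(off), off)
    return "interstitial", nearest[1] if nearest else 0


def assign_deletion_class(
    interval: Optional[GenomeInterval],
    lcr_map: LCRMap,
    patient: str = "",
    depth_ratio: float = float("nan"),
) -> DeletionCall:
    """Name the deletion by its anchoring LCRs.

    Both endpoints in LCRs X and Y give class "XY". A start between LCR-A
    and LCR-B (outside both) ending in LCR-B is the atypical "A+B"; a
    start in LCR-A ending between LCR-B and LCR-C (outside both) is the
    atypical "AC-". Any other interstitial combination is
    "atypical-other".
    """
    if interval is None:
        return DeletionCall(patient, None, "none", depth_ratio=depth_ratio)
    s_name, s_off = _anchor(interval.start, lcr_map)
    e_name, e_off = _anchor(interval.end, lcr_map)
    a = lcr_map.interval("A")
    b = lcr_map.interval("B")
    c = lcr_map.interval("C")
    if s_name != "interstitial" and e_name != "interstitial":
        label = s_name + e_name
    elif (
        s_name == "interstitial"
        and a.end < interval.start < b.start
        and e_name == "B"
    ):
        label = "A+B"
    elif (
        s_name == "A"
        and e_name == "interstitial"
        and b.end < interval.end < c.start
    ):
        label = "AC-"
    else:
        label = "atypical-other"
    return DeletionCall(
        patient,
        interval,
        label,
        start_anchor=(s_name, s_off),
        end_anchor=(e_name, e_off),
        depth_ratio=depth_ratio,
    )


def detect_nullisomy(
    bins: CoverageBins,
    deletion: GenomeInterval,
    params: SegmentationParams = SegmentationParams(),
) -> list[GenomeInterval]:
    """Screen the deleted interval for loss of the remaining allele.

    Returns maximal runs of unflagged bins inside the deletion with mean
    depth at or below ``null_depth_max`` spanning at least
    ``null_min_len`` bp.
    """
    unflagged = ~bins.flagged
    ends = bins.starts + bins.bin_size - 1
    inside = (bins.starts >= deletion.start) & (ends <= deletion.end)
    null = unflagged & inside & (bins.means <= params.null_depth_max)
    out: list[GenomeInterval] = []
    i = 0
    n = len(null)
    while i < n:
        if null[i]:
            j = i
            while j + 1 < n and null[j + 1]:
                j += 1
            iv = GenomeInterval(bins.region.contig, int(bins.starts[i]), bins.bin_end(j))
            if iv.length >= params.null_min_len:
                out.append(iv)
            i = j + 1
        else:
            i += 1
    return out


def type_patient(
    patient_id: str,
    depth: np.ndarray,
    calls: Sequence[CallRecord],
    region: RegionModel,
    params: SegmentationParams = SegmentationParams(),
    bin_size: int = 100,
    window: int = 50_000,
    threshold: float = 70.0,
) -> DeletionCall:
    """Convenience wrapper: bin, window, segment, classify, screen."""
    bins = bin_coverage(depth, region.span, region.segdups, bin_size)
    zyg = zygosity_windows(calls, region.span, window, threshold)
    interval = segment_hemizygous(bins, zyg, params)
    unflagged = ~bins.flagged
    ratio = float("nan")
    if interval is not None and unflagged.any():
        ends = bins.starts + bins.bin_size - 1
        in_run = (bins.starts >= interval.start) & (ends <= interval.end)
        outside = unflagged & ~in_run
        if outside.any() and (in_run & unflagged).any():
            ratio = float(
                np.mean(bins.means[in_run & unflagged])
                / np.median(bins.means[outside])
            )
    call = assign_deletion_class(interval, region.lcr_map, patient_id, ratio)
    if interval is not None:
        call.nullisomy = detect_nullisomy(bins, interval, params)
    return call
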