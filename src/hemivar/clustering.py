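"""Capture-platform batch-effect check via UPGMA on pseudo-sequences.

Each patient of a chosen deletion class is turned into a pseudo-sequence
over the class's shared catalog positions: V where the patient carries a
kept homozygous-alt call, R where the caller emitted a confident
reference call, N otherwise. Pairwise p-distances are computed with
pairwise deletion (per pair, only sites where neither symbol is N), a
UPGMA tree is built, and a platform-segregation purity score quantifies
whether the tree splits by capture platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .calls import CallClass, CallRecord, classify_call

__all__ = [
    "PseudoSequence",
    "DistanceMatrix",
    "ClusterNode",
    "build_pseudosequences",
    "pdistance_pairwise_deletion",
    "distance_matrix",
    "upgma",
    "platform_segregation_score",
    "to_newick",
    "write_phylip",
]


@dataclass
class PseudoSequence:
    patient: str
    platform: str
    symbols: str  # over {R, V, N}, ordered by position

    def __post_init__(self) -> None:
        bad = set(self.symbols) - set("RVN")
        if bad:
            raise ValueError(f"invalid pseudo-sequence symbols: {sorted(bad)}")


def build_pseudosequences(
    call_sets: Mapping[str, Sequence[CallRecord]],
    kept_positions: Mapping[str, set[int]],
    positions: Sequence[int],
    platforms: Optional[Mapping[str, str]] = None,
    threshold: float = 70.0,
) -> list[PseudoSequence]:
    """Build one equal-length pseudo-sequence per patient.

    ``call_sets`` holds each patient's full classified call set (reference
    emissions included); ``kept_positions`` the positions of their kept
    hemizygous hom-alt calls. At each shared position the symbol is V for
    a kept hom-alt call, R for a reference call, N otherwise
    (indeterminable, heterozygous, or never emitted).
    """
    positions = sorted(positions)
    index = {p: i for i, p in enumerate(positions)}
    out = []
    for pid, calls in call_sets.items():
        symbols = ["N"] * len(positions)
        for c in calls:
            i = index.get(c.position)
            if i is None:
                continue
            if c.position in kept_positions.get(pid, set()):
                symbols[i] = "V"
            elif classify_call(c.pl, threshold) is CallClass.LIKELY_REFERENCE:
                if symbols[i] == "N":
                    symbols[i] = "R"
        platform = platforms.get(pid, "") if platforms else (
            calls[0].platform if calls else ""
        )
        out.append(PseudoSequence(pid, platform, "".join(symbols)))
    return out


def pdistance_pairwise_deletion(
    a: PseudoSequence, b: PseudoSequence
) -> tuple[Optional[float], int]:
    """Proportion of mismatches among sites where neither symbol is N.

    Returns (distance, n_comparable); distance is None when no site is
    comparable.
    """
    if len(a.symbols) != len(b.symbols):
        raise ValueError(
            f"pseudo-sequence length mismatch: {len(a.symbols)} vs {len(b.symbols)}"
        )
    sa = np.frombuffer(a.symbols.encode(), dtype="S1")
    sb = np.frombuffer(b.symbols.encode(), dtype="S1")
    comparable = (sa != b"N") & (sb != b"N")
    n = int(comparable.sum())
    if n == 0:
        return None, 0
    mism = int((sa[comparable] != sb[comparable]).sum())
    return mism / n, n


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # float matrix; NaN marks missing
    n_comparable: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise ValueError("distance matrix must be symmetric")

    @property
    def has_missing(self) -> bool:
        off = ~np.eye(len(self.labels), dtype=bool)
        return bool(np.isnan(self.d[off]).any())


def distance_matrix(seqs: Sequence[PseudoSequence]) -> DistanceMatrix:
    n = len(seqs)
    d = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = len(seqs[i].symbols)
        for j in range(i + 1, n):
            dist, m = pdistance_pairwise_deletion(seqs[i], seqs[j])
            d[i, j] = d[j, i] = np.nan if dist is None else dist
            counts[i, j] = counts[j, i] = m
    return DistanceMatrix([s.patient for s in seqs], d, counts)


@dataclass
class ClusterNode:
    """Node of a rooted ultrametric tree; leaf height is 0."""

    height: float
    label: Optional[str] = None
    children: list["ClusterNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def n_leaves(self) -> int:
        return len(self.leaves())


def upgma(dmat: DistanceMatrix) -> ClusterNode:
    """Unweighted pair group method with arithmetic mean.

    Iteratively joins the closest pair of clusters at height d/2; the
    distance from a merged cluster to any other is the size-weighted mean
    of its members' distances (equivalently, the plain mean over all
    cross-cluster leaf pairs of the input matrix). Ties are broken by the
    lexicographically smallest (label, label) pair, using each cluster's
    smallest member label. Missing entries are a hard error: impute or
    subset the matrix first.
    """
    if dmat.has_missing:
        raise ValueError(
            "distance matrix has missing entries; impute them or drop the "
            "patients with no comparable sites before clustering"
        )
    n = len(dmat.labels)
    if n == 0:
        raise ValueError("empty distance matrix")
    nodes = [ClusterNode(0.0, label=lab) for lab in dmat.labels]
    sizes = [1] * n
    keys = [lab for lab in dmat.labels]  # smallest member label per cluster
    d = dmat.d.astype(float).copy()
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (d[i, j], pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dist, _, i, j = best
        merged = ClusterNode(dist / 2.0, children=[nodes[i], nodes[j]])
        new_size = sizes[i] + sizes[j]
        # size-weighted arithmetic mean update
        for k in active:
            if k in (i, j):
                continue
            d_new = (sizes[i] * d[i, k] + sizes[j] * d[j, k]) / new_size
            d[i, k] = d[k, i] = d_new
        nodes[i] = merged
        sizes[i] = new_size
        keys[i] = min(keys[i], keys[j])
        active.remove(j)
    return nodes[active[0]]


def cut_tree(root: ClusterNode, k: int) -> list[ClusterNode]:
    """Cut at the highest k-1 joins, yielding k clusters."""
    n = root.n_leaves()
    if k > n:
        raise ValueError(f"cannot cut {n} leaves into {k} clusters")
    clusters = [root]
    while len(clusters) < k:
        tallest = max(
            (c for c in clusters if not c.is_leaf), key=lambda c: c.height, default=None
        )
        if tallest is None:
            break
        clusters.remove(tallest)
        clusters.extend(tallest.children)
    return clusters


def platform_segregation_score(
    root: ClusterNode, platforms: Mapping[str, str], k: int = 2
) -> float:
    """Purity of a k-cluster cut with respect to platform labels.

    Purity is the unweighted mean over clusters of the majority-label
    fraction: 1.0 means the cut separates the platforms perfectly; values
    near the prevalence of the majority label mean no segregation.
    """
    labels = set(platforms.values())
    if len(labels) < 2:
        raise ValueError("need two platform labels to score segregation")
    clusters = cut_tree(root, k)
    fracs = []
    for c in clusters:
        leaf_labels = [platforms[leaf] for leaf in c.leaves()]
        top = max(leaf_labels.count(l) for l in labels)
        fracs.append(top / len(leaf_labels))
    return float(np.mean(fracs))


def to_newick(root: ClusterNode) -> str:
    """Newick string with branch lengths = height differences."""

    def fmt(node: ClusterNode, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{bl:.6f}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}):{bl:.6f}"

    inner = ",".join(fmt(c, root.height) for c in root.children)
    return f"({inner});"


def write_phylip(path, dmat: DistanceMatrix) -> None:
    """Write the distance matrix in relaxed PHYLIP format."""
    with open(path, "w") as fh:
        fh.write(f"{len(dmat.labels)}\n")
        for i, lab in enumerate(dmat.labels):
            row = " ".join(f"{x:.6f}" for x in dmat.d[i])
            fh.write(f"{lab}  {row}\n")
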