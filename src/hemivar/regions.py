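"""Genomic region description shared by all pipeline stages.

Holds the low-copy-repeat (LCR) map, gene models, segmental-duplication
mask, per-base conservation track and known-variant/allele-frequency table
for a single contig, plus the interval and coordinate utilities the other
stages rely on.

Coordinates are 1-based inclusive throughout (the VCF convention); BED
input/output converts at the boundary (BED is 0-based half-open).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeInterval",
    "LCRMap",
    "GeneModel",
    "SegDupMask",
    "ConservationTrack",
    "KnownVariantTable",
    "RegionModel",
    "in_mask",
    "functional_category",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_conservation",
    "read_known_variants",
    "load_region",
]

CATEGORIES = ("coding_exonic", "noncoding_exonic", "intronic", "intergenic")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Closed interval [start, end] on one contig, 1-based inclusive."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end < start: [{self.start}, {self.end}] on {self.contig}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersection(self, other: "GenomeInterval") -> Optional["GenomeInterval"]:
        if not self.overlaps(other):
            return None
        return GenomeInterval(
            self.contig, max(self.start, other.start), min(self.end, other.end)
        )


def merge_intervals(intervals: Iterable[GenomeInterval]) -> list[GenomeInterval]:
    """Sort and merge overlapping or touching intervals on a single contig."""
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[GenomeInterval] = []
    for iv in ivs:
        if merged and merged[-1].contig != iv.contig:
            raise ValueError("cannot merge intervals from mixed contigs")
        if merged and iv.start <= merged[-1].end + 1:
            prev = merged.pop()
            merged.append(
                GenomeInterval(prev.contig, prev.start, max(prev.end, iv.end))
            )
        else:
            merged.append(iv)
    return merged


@dataclass
class LCRMap:
    """Ordered map of the four low-copy repeats flanking 22q11 deletions.

    ``breakpoint_tolerance_bp`` widens each LCR when anchoring deletion
    endpoints: a breakpoint within the LCR interval +/- the tolerance is
    considered mediated by that LCR.
    """

    lcrs: list[tuple[str, GenomeInterval]]
    breakpoint_tolerance_bp: int = 10_000

    def __post_init__(self) -> None:
        names = [name for name, _ in self.lcrs]
        if len(set(names)) != len(names):
            raise ValueError(f"LCR names not unique: {names}")
        if self.breakpoint_tolerance_bp <= 0:
            raise ValueError("breakpoint tolerance must be > 0")
        self.lcrs = sorted(self.lcrs, key=lambda nv: nv[1].start)
        for (_, a), (_, b) in zip(self.lcrs, self.lcrs[1:]):
            if a.overlaps(b):
                raise ValueError("LCR intervals must not overlap")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.lcrs]

    def interval(self, name: str) -> GenomeInterval:
        for n, iv in self.lcrs:
            if n == name:
                return iv
        raise KeyError(name)


@dataclass
class GeneModel:
    """RefSeq-style gene: exon intervals plus the coding subset of them."""

    name: str
    strand: str
    exons: list[GenomeInterval]
    coding: list[GenomeInterval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.coding = sorted(self.coding, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.overlaps(b):
                raise ValueError(f"gene {self.name}: exons overlap")
        for civ in self.coding:
            if not any(
                ex.start <= civ.start and civ.end <= ex.end for ex in self.exons
            ):
                raise ValueError(
                    f"gene {self.name}: coding interval [{civ.start}, {civ.end}] "
                    "not contained in any exon"
                )

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.exons[0].contig, self.exons[0].start, self.exons[-1].end
        )

    def position_category(self, pos: int) -> Optional[str]:
        """Category of ``pos`` relative to this gene, or None if outside."""
        if not self.span.contains(pos):
            return None
        for civ in self.coding:
            if civ.contains(pos):
                return "coding_exonic"
        for ex in self.exons:
            if ex.contains(pos):
                return "noncoding_exonic"
        return "intronic"


class SegDupMask:
    """Merged, sorted segmental-duplication intervals with fast lookup."""

    def __init__(self, intervals: Iterable[GenomeInterval]):
        self.intervals = merge_intervals(intervals)
        self._starts = [iv.start for iv in self.intervals]
        self._ends = [iv.end for iv in self.intervals]

    def __contains__(self, pos: int) -> bool:
        i = bisect.bisect_right(self._starts, pos) - 1
        return i >= 0 and pos <= self._ends[i]

    def overlaps(self, interval: GenomeInterval) -> bool:
        return any(iv.overlaps(interval) for iv in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def in_mask(pos: int, mask: SegDupMask) -> bool:
    """True iff ``pos`` falls inside any mask interval (inclusive ends)."""
    return pos in mask


class ConservationTrack:
    """Per-base conservation scores over a contiguous span."""

    def __init__(self, start: int, scores: np.ndarray):
        scores = np.asarray(scores, dtype=float)
        if not np.all(np.isfinite(scores)):
            raise ValueError("conservation scores must be finite")
        self.start = int(start)
        self.scores = scores

    @property
    def end(self) -> int:
        return self.start + len(self.scores) - 1

    def score(self, pos: int) -> float:
        if not (self.start <= pos <= self.end):
            raise KeyError(f"position {pos} outside conservation track")
        return float(self.scores[pos - self.start])

    def slice(self, interval: GenomeInterval) -> np.ndarray:
        lo = max(interval.start, self.start) - self.start
        hi = min(interval.end, self.end) - self.start + 1
        return self.scores[lo:hi]


class KnownVariantTable:
    """Known variants keyed by (position, ref, alt) with population AF."""

    def __init__(self, records: Mapping[tuple[int, str, str], float]):
        for key, af in records.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency out of [0,1] at {key}: {af}")
        self.records = dict(records)

    def frequency(self, pos: int, ref: str, alt: str) -> Optional[float]:
        return self.records.get((pos, ref, alt))

    def is_annotated(self, pos: int, ref: str, alt: str) -> bool:
        return (pos, ref, alt) in self.records

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class RegionModel:
    """All annotation tracks over the single study contig."""

    contig: str
    span: GenomeInterval
    lcr_map: LCRMap
    genes: list[GeneModel]
    segdups: SegDupMask
    conservation: Optional[ConservationTrack] = None
    known_variants: Optional[KnownVariantTable] = None
    # reference bases as a numpy byte-char array aligned to span, or None
    sequence: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: g.span.start)
        contigs = {self.span.contig}
        contigs.update(iv.contig for _, iv in self.lcr_map.lcrs)
        contigs.update(g.span.contig for g in self.genes)
        contigs.update(iv.contig for iv in self.segdups.intervals)
        if contigs != {self.contig}:
            raise ValueError(f"mixed contigs in region model: {sorted(contigs)}")

    def base(self, pos: int) -> str:
        if self.sequence is None:
            raise ValueError("region model carries no reference sequence")
        return chr(self.sequence[pos - self.span.start])

    def intergenic_blocks(self) -> list[GenomeInterval]:
        """Maximal blocks between consecutive gene spans (and region edges)."""
        blocks: list[GenomeInterval] = []
        cursor = self.span.start
        for g in self.genes:
            if g.span.start > cursor:
                blocks.append(GenomeInterval(self.contig, cursor, g.span.start - 1))
            cursor = max(cursor, g.span.end + 1)
        if cursor <= self.span.end:
            blocks.append(GenomeInterval(self.contig, cursor, self.span.end))
        return blocks


def functional_category(pos: int, genes: Sequence[GeneModel]) -> str:
    """Classify a position into exactly one functional category.

    Precedence when a position hits multiple overlapping genes:
    coding_exonic > noncoding_exonic (UTR) > intronic > intergenic.
    """
    best = "intergenic"
    rank = {c: i for i, c in enumerate(CATEGORIES)}
    for gene in genes:
        cat = gene.position_category(pos)
        if cat is not None and rank[cat] < rank[best]:
            best = cat
    return best


# ---------------------------------------------------------------------------
# File I/O: BED (0-based half-open), flat gene table, conservation, known AFs
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomeInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            contig, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            if end0 <= start0:
                raise ValueError(
                    f"{path}:{lineno}: BED end <= start ({start0}, {end0})"
                )
            intervals.append(GenomeInterval(contig, start0 + 1, end0))
    return intervals


def write_bed(
    path: str | Path,
    intervals: Iterable[GenomeInterval],
    names: Optional[Sequence[str]] = None,
) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.contig, str(iv.start - 1), str(iv.end)]
            if names is not None:
                row.append(str(names[i]))
            fh.write("\t".join(row) + "\n")


def _csv_ints(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a RefSeq-like flat gene table.

    Columns (tab separated, header required): gene, contig, strand,
    exonStarts, exonEnds (comma lists, 0-based half-open), cdsStart, cdsEnd
    (0-based half-open; cdsStart == cdsEnd means non-coding).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for _, row in df.iterrows():
        contig = row["contig"]
        starts = _csv_ints(row["exonStarts"])
        ends = _csv_ints(row["exonEnds"])
        exons = [GenomeInterval(contig, s + 1, e) for s, e in zip(starts, ends)]
        cds_start, cds_end = int(row["cdsStart"]), int(row["cdsEnd"])
        coding: list[GenomeInterval] = []
        if cds_end > cds_start:
            cds = GenomeInterval(contig, cds_start + 1, cds_end)
            coding = [x for x in (ex.intersection(cds) for ex in exons) if x]
        genes.append(GeneModel(row["gene"], row["strand"], exons, coding))
    return genes


def write_gene_table(path: str | Path, genes: Iterable[GeneModel]) -> None:
    rows = []
    for g in genes:
        cds_start = g.coding[0].start - 1 if g.coding else g.span.start - 1
        cds_end = g.coding[-1].end if g.coding else g.span.start - 1
        rows.append(
            {
                "gene": g.name,
                "contig": g.span.contig,
                "strand": g.strand,
                "exonStarts": ",".join(str(iv.start - 1) for iv in g.exons),
                "exonEnds": ",".join(str(iv.end) for iv in g.exons),
                "cdsStart": cds_start,
                "cdsEnd": cds_end,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_conservation(path: str | Path) -> ConservationTrack:
    """Read a 2-column (pos, score) tab-separated conservation file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["pos", "score"])
    pos = df["pos"].to_numpy(dtype=int)
    if len(pos) == 0:
        raise ValueError(f"{path}: empty conservation file")
    if not np.array_equal(pos, np.arange(pos[0], pos[0] + len(pos))):
        raise ValueError(f"{path}: conservation positions must be contiguous")
    return ConservationTrack(int(pos[0]), df["score"].to_numpy(dtype=float))


def read_known_variants(path: str | Path) -> KnownVariantTable:
    """Read a 4-column (pos, ref, alt, af) tab-separated table with header."""
    df = pd.read_csv(path, sep="\t", dtype={"pos": int, "af": float})
    records = {
        (int(r.pos), str(r.ref), str(r.alt)): float(r.af) for r in df.itertuples()
    }
    return KnownVariantTable(records)


def load_region(
    *,
    span: GenomeInterval,
    lcr_bed: str | Path,
    gene_table: str | Path,
    segdup_bed: str | Path,
    conservation_path: Optional[str | Path] = None,
    known_variants_path: Optional[str | Path] = None,
    breakpoint_tolerance_bp: int = 10_000,
) -> RegionModel:
    """Assemble a RegionModel from on-disk annotation tracks.

    The LCR BED must carry interval names (A-D) in column 4. All tracks
    must be on the span's contig; mixed contigs are a hard error.
    """
    lcr_records = []
    with open(lcr_bed) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{lcr_bed}:{lineno}: LCR BED needs a name column")
            iv = GenomeInterval(fields[0], int(fields[1]) + 1, int(fields[2]))
            lcr_records.append((fields[3], iv))
    lcr_map = LCRMap(lcr_records, breakpoint_tolerance_bp=breakpoint_tolerance_bp)
    genes = read_gene_table(gene_table)
    segdups = SegDupMask(read_bed(segdup_bed))
    conservation = (
        read_conservation(conservation_path) if conservation_path else None
    )
    known = read_known_variants(known_variants_path) if known_variants_path else None
    return RegionModel(
        contig=span.contig,
        span=span,
        lcr_map=lcr_map,
        genes=genes,
        segdups=segdups,
        conservation=conservation,
        known_variants=known,
    )
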