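"""Synthetic 22q11-like cohort generator with known truth.

Builds a scaled-down single-contig region carrying four low-copy repeats
(LCR A-D), genes tiled between them, segmental duplications inside the
LCRs, a conservation track and a known-variant table — then simulates
patients with LCR-mediated or atypical deletions, Poisson depth tracks,
and PL-bearing emit-all-sites call sets, including heterozygous artifact
calls inside the hemizygous region at a configurable rate.

The defaults mirror the study conditions of a 127-patient targeted
resequencing cohort: class mix 8 AB / 2 AC / 111 AD / 4 BD plus one
atypical A+B and one atypical AC- deletion, two capture platforms
(72 vs 55 patients) whose per-patient heterozygous-artifact fractions
average 11.6% and 24.3% of hemizygous variant calls, and a per-patient
hemizygous variant density of ~5.8e-4 per bp (about 1,500 variants over a
2.65 Mb AD deletion). The synthetic region is 800 kb so a full cohort
simulates in seconds; densities, depth and rates are kept at study scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .calls import CallRecord, PLTriple
from .regions import (
    ConservationTrack,
    GeneModel,
    GenomeInterval,
    KnownVariantTable,
    LCRMap,
    RegionModel,
    SegDupMask,
    write_bed,
    write_gene_table,
)

__all__ = [
    "PlatformSpec",
    "CohortSpec",
    "PoolVariant",
    "TruthEntry",
    "TruthSet",
    "Patient",
    "Cohort",
    "simulate_region",
    "simulate_patient",
    "simulate_cohort",
    "write_fixtures",
    "DELETION_CLASSES",
]

DELETION_CLASSES = ("AB", "AC", "AD", "BD", "A+B", "AC-", "none")

#: Class mix of the emulated cohort (counts out of 127 patients).
DEFAULT_CLASS_PROBS = {
    "AB": 8 / 127,
    "AC": 2 / 127,
    "AD": 111 / 127,
    "BD": 4 / 127,
    "A+B": 1 / 127,
    "AC-": 1 / 127,
    "none": 0.0,
}


@dataclass(frozen=True)
class PlatformSpec:
    """One capture platform: sampling probability and modifiers."""

    prob: float
    depth_mult: float = 1.0
    # multiplier on the cohort-level het artifact rate
    artifact_mult: float = 1.0


def _default_platforms() -> dict[str, PlatformSpec]:
    # 72/127 vs 55/127 patients; artifact fractions 11.6% vs 24.3% of
    # hemizygous variant calls -> multipliers relative to the 11.6% base.
    return {
        "nimblegen": PlatformSpec(prob=72 / 127, depth_mult=1.0, artifact_mult=1.0),
        "agilent": PlatformSpec(
            prob=55 / 127, depth_mult=0.85, artifact_mult=0.243 / 0.116
        ),
    }


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort."""

    n_patients: int = 127
    deletion_class_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS)
    )
    region_length: int = 800_000
    n_genes: int = 40
    diploid_depth_mean: float = 80.0
    hemizygous_depth_factor: float = 0.5
    het_artifact_rate: float = 0.116
    variant_rate: float = 5.8e-4  # expected variants per bp per haplotype
    rare_fraction: float = 0.6  # fraction of pool variants with AF <= 0.05
    platform_labels: Mapping[str, PlatformSpec] = field(
        default_factory=_default_platforms
    )
    seed: int = 0
    # secondary knobs
    low_conf_rate: float = 0.03  # carrier calls emitted with all PLs <= 70
    ref_emit_prob: float = 0.9  # non-carrier pool sites emitted as reference
    insertion_fraction: float = 0.01  # pool variants that are insertions
    annotated_fraction: float = 0.84  # pool variants present in the AF panel
    breakpoint_tolerance_bp: int = 10_000
    n_hard_blocks: int = 3  # poorly capturable blocks shared by all samples
    hard_block_len: int = 2_000
    gene_density_multipliers: Mapping[str, float] = field(default_factory=dict)
    contig: str = "chr22s"

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        total = sum(self.deletion_class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"deletion class probabilities sum to {total}, not 1")
        for name in self.deletion_class_probs:
            if name not in DELETION_CLASSES:
                raise ValueError(f"unknown deletion class {name!r}")
        for rate in (
            self.het_artifact_rate,
            self.variant_rate,
            self.rare_fraction,
            self.low_conf_rate,
            self.ref_emit_prob,
            self.insertion_fraction,
            self.annotated_fraction,
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate out of [0,1]: {rate}")
        if not (0.0 < self.hemizygous_depth_factor < 1.0):
            raise ValueError("hemizygous_depth_factor must be in (0,1)")


@dataclass(frozen=True)
class PoolVariant:
    """A population variant: the cohort draws carrier status from its AF."""

    position: int
    ref: str
    alt: str
    af: float
    annotated: bool


@dataclass
class TruthEntry:
    patient: str
    platform: str
    deletion_class: str
    interval: Optional[GenomeInterval]
    variant_positions: frozenset[int]


@dataclass
class TruthSet:
    entries: dict[str, TruthEntry]
    gene_density_multipliers: dict[str, float]


@dataclass
class Patient:
    patient_id: str
    platform: str
    depth: np.ndarray  # per-base, aligned to region span
    calls: list[CallRecord]
    truth: TruthEntry


@dataclass
class Cohort:
    spec: CohortSpec
    region: RegionModel
    pool: list[PoolVariant]
    patients: list[Patient]
    truth: TruthSet


# ---------------------------------------------------------------------------
# Region construction
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _region_layout(spec: CohortSpec) -> tuple[LCRMap, list[GenomeInterval]]:
    """Place the four LCRs at fixed fractions of the region length."""
    L = spec.region_length
    width = int(L * 0.05)
    if L < 200_000:
        raise ValueError("region too small to fit 4 LCRs and genes (need >=200 kb)")
    starts = [int(L * f) + 1 for f in (0.0625, 0.3125, 0.5625, 0.8125)]
    contig = spec.contig
    lcrs = [
        (name, GenomeInterval(contig, s, s + width - 1))
        for name, s in zip("ABCD", starts)
    ]
    # segmental duplications occupy an off-center chunk of each LCR, so the
    # true breakpoints (mid-LCR) stay in unmasked sequence
    segdups = [
        GenomeInterval(contig, iv.start + int(width * 0.10), iv.start + int(width * 0.35))
        for _, iv in lcrs
    ]
    return LCRMap(lcrs, breakpoint_tolerance_bp=spec.breakpoint_tolerance_bp), segdups


def _tile_genes(spec: CohortSpec, lcr_map: LCRMap) -> list[GeneModel]:
    """Tile genes into the three inter-LCR gaps, round-robin."""
    if spec.n_genes == 0:
        return []
    contig = spec.contig
    gaps = []
    for (_, a), (_, b) in zip(lcr_map.lcrs, lcr_map.lcrs[1:]):
        gaps.append((a.end + 5_000, b.start - 5_000))
    per_gap = [spec.n_genes // 3] * 3
    for i in range(spec.n_genes % 3):
        per_gap[i] += 1
    genes: list[GeneModel] = []
    idx = 0
    for (lo, hi), n in zip(gaps, per_gap):
        if n == 0:
            continue
        slot = (hi - lo + 1) // n
        for j in range(n):
            span_start = lo + j * slot + slot // 10
            span_len = int(slot * 0.7)
            n_exons = 4
            exon_len = max(span_len // 10, 150)
            gap_len = (span_len - n_exons * exon_len) // (n_exons - 1)
            exons = []
            for k in range(n_exons):
                s = span_start + k * (exon_len + gap_len)
                exons.append(GenomeInterval(contig, s, s + exon_len - 1))
            # UTRs: first 150 bp of first exon and last 150 bp of last exon
            coding = []
            for k, ex in enumerate(exons):
                s, e = ex.start, ex.end
                if k == 0:
                    s += 150
                if k == n_exons - 1:
                    e -= 150
                coding.append(GenomeInterval(contig, s, e))
            # trim the coding end so the CDS length is a multiple of 3
            total = sum(iv.length for iv in coding)
            trim = total % 3
            if trim:
                last = coding[-1]
                coding[-1] = GenomeInterval(contig, last.start, last.end - trim)
            strand = "+" if idx % 3 else "-"
            genes.append(GeneModel(f"GENE{idx:03d}", strand, exons, coding))
            idx += 1
    return genes


def _draw_pool(
    spec: CohortSpec, rng: np.random.Generator, genes: Sequence[GeneModel], seq: np.ndarray
) -> list[PoolVariant]:
    """Sample the population variant pool over the region.

    Pool density is chosen so that the expected per-patient hemizygous
    variant density (sum of allele frequencies per bp) equals
    ``spec.variant_rate``.
    """
    mean_rare_af = (0.002 + 0.05) / 2
    mean_common_af = (0.05 + 0.5) / 2
    mean_af = spec.rare_fraction * mean_rare_af + (1 - spec.rare_fraction) * mean_common_af
    pool_rate = spec.variant_rate / mean_af
    L = spec.region_length
    n_pool = rng.poisson(pool_rate * L)
    positions = np.sort(rng.choice(L, size=min(n_pool, L), replace=False)) + 1

    # per-position density multiplier from gene tolerance settings
    keep = np.ones(len(positions), dtype=bool)
    if spec.gene_density_multipliers:
        for g in genes:
            mult = spec.gene_density_multipliers.get(g.name)
            if mult is None or mult >= 1.0:
                continue
            inside = (positions >= g.span.start) & (positions <= g.span.end)
            drop = inside & (rng.random(len(positions)) >= mult)
            keep &= ~drop
    positions = positions[keep]

    rare = rng.random(len(positions)) < spec.rare_fraction
    afs = np.where(
        rare,
        rng.uniform(0.002, 0.05, len(positions)),
        rng.uniform(0.05, 0.5, len(positions)),
    )
    annotated = rng.random(len(positions)) < spec.annotated_fraction
    is_ins = rng.random(len(positions)) < spec.insertion_fraction

    pool = []
    for pos, af, ann, ins in zip(positions, afs, annotated, is_ins):
        ref = chr(seq[pos - 1])
        if ins:
            n_extra = int(rng.integers(1, 3))
            extra = "".join(chr(b) for b in rng.choice(_BASES, size=n_extra))
            alt = ref + extra
        else:
            choices = [b for b in "ACGT" if b != ref]
            alt = choices[int(rng.integers(0, 3))]
        pool.append(PoolVariant(int(pos), ref, alt, float(af), bool(ann)))
    return pool


def simulate_region(spec: CohortSpec) -> tuple[RegionModel, list[PoolVariant], list[GenomeInterval]]:
    """Build the deterministic synthetic region, variant pool and hard blocks.

    Returns the region model, the population variant pool, and the list of
    poorly-capturable blocks (near-zero depth in every sample).
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    lcr_map, segdup_ivs = _region_layout(spec)
    genes = _tile_genes(spec, lcr_map)
    contig = spec.contig
    span = GenomeInterval(contig, 1, spec.region_length)
    seq = rng.choice(_BASES, size=spec.region_length)

    # conservation: mild noise, elevated in coding bases
    cons = rng.normal(0.0, 0.5, spec.region_length)
    for g in genes:
        for civ in g.coding:
            cons[civ.start - 1 : civ.end] += rng.normal(3.0, 0.5)
    conservation = ConservationTrack(1, cons)

    pool = _draw_pool(spec, rng, genes, seq)
    known = KnownVariantTable(
        {(v.position, v.ref, v.alt): v.af for v in pool if v.annotated}
    )

    # hard-to-capture blocks, placed in the A-D interior away from LCRs and
    # away from every class's true breakpoints (so edge recovery is exact)
    hard_blocks = []
    lcr_expanded = [
        (iv.start - spec.hard_block_len, iv.end + spec.hard_block_len)
        for _, iv in lcr_map.lcrs
    ]
    for cls in DELETION_CLASSES:
        iv = true_deletion_interval(cls, lcr_map, contig)
        if iv is not None:
            pad = 5_000 + spec.hard_block_len
            lcr_expanded.append((iv.start - pad, iv.start + pad))
            lcr_expanded.append((iv.end - pad, iv.end + pad))
    lo, hi = lcr_map.interval("A").end, lcr_map.interval("D").start
    tries = 0
    while len(hard_blocks) < spec.n_hard_blocks and tries < 100:
        tries += 1
        s = int(rng.integers(lo + 10_000, hi - 10_000 - spec.hard_block_len))
        if any(a <= s <= b or a <= s + spec.hard_block_len <= b for a, b in lcr_expanded):
            continue
        hard_blocks.append(GenomeInterval(contig, s, s + spec.hard_block_len - 1))

    region = RegionModel(
        contig=contig,
        span=span,
        lcr_map=lcr_map,
        genes=genes,
        segdups=SegDupMask(segdup_ivs),
        conservation=conservation,
        known_variants=known,
        sequence=seq,
    )
    return region, pool, hard_blocks


# ---------------------------------------------------------------------------
# Patient simulation
# ---------------------------------------------------------------------------


def true_deletion_interval(
    class_draw: str, lcr_map: LCRMap, contig: str
) -> Optional[GenomeInterval]:
    """Truth interval for a deletion class; breakpoints sit mid-LCR.

    The two atypical classes place one breakpoint well outside any LCR:
    A+B starts 60 kb downstream of LCR-A's end; AC- ends 70 kb upstream of
    LCR-C's start (past LCR-B).
    """
    if class_draw == "none":
        return None
    mids = {
        name: (iv.start + iv.end) // 2 + 37 for name, iv in lcr_map.lcrs
    }  # +37 keeps breakpoints off bin boundaries
    a_end = lcr_map.interval("A").end
    c_start = lcr_map.interval("C").start
    table = {
        "AB": (mids["A"], mids["B"]),
        "AC": (mids["A"], mids["C"]),
        "AD": (mids["A"], mids["D"]),
        "BD": (mids["B"], mids["D"]),
        "A+B": (a_end + 60_000 + 37, mids["B"]),
        "AC-": (mids["A"], c_start - 70_000 + 37),
    }
    start, end = table[class_draw]
    return GenomeInterval(contig, start, end)


def _variant_pl(rng: np.random.Generator) -> PLTriple:
    return PLTriple(float(rng.integers(80, 250)), float(rng.integers(71, 180)), 0.0)


def _het_pl(rng: np.random.Generator) -> PLTriple:
    return PLTriple(float(rng.integers(71, 200)), 0.0, float(rng.integers(71, 200)))


def _lowconf_pl(rng: np.random.Generator) -> PLTriple:
    return PLTriple(float(rng.integers(1, 70)), float(rng.integers(1, 70)), 0.0)


def _ref_pl(rng: np.random.Generator) -> PLTriple:
    return PLTriple(0.0, float(rng.integers(71, 150)), float(rng.integers(100, 250)))


def simulate_patient(
    spec: CohortSpec,
    region: RegionModel,
    pool: Sequence[PoolVariant],
    hard_blocks: Sequence[GenomeInterval],
    class_draw: str,
    patient_id: str,
    platform: str,
    rng: np.random.Generator,
) -> Patient:
    """Simulate one patient's depth track and emit-all-sites call set.

    Depth is Poisson per base: diploid mean outside the deletion, mean
    times ``hemizygous_depth_factor`` inside. Carrier status at each pool
    variant is drawn from its allele frequency — one draw inside the
    deletion (single allele), Hardy-Weinberg outside.
    """
    pspec = spec.platform_labels[platform]
    deletion = true_deletion_interval(class_draw, region.lcr_map, region.contig)
    L = spec.region_length

    mean = spec.diploid_depth_mean * pspec.depth_mult
    lam = np.full(L, mean)
    if deletion is not None:
        lam[deletion.start - 1 : deletion.end] = mean * spec.hemizygous_depth_factor
    for blk in hard_blocks:
        lam[blk.start - 1 : blk.end] = 0.3
    depth = rng.poisson(lam).astype(np.int16)

    artifact_rate = min(spec.het_artifact_rate * pspec.artifact_mult, 1.0)
    calls: list[CallRecord] = []
    true_positions: set[int] = set()
    u_carrier = rng.random(len(pool))
    for v, u in zip(pool, u_carrier):
        pos = v.position
        inside = deletion is not None and deletion.contains(pos)
        if inside:
            if u < v.af:  # carrier on the single remaining allele
                true_positions.add(pos)
                r = rng.random()
                if r < artifact_rate:
                    pl = _het_pl(rng)  # mosaicism/artifact: looks heterozygous
                elif r < artifact_rate + spec.low_conf_rate:
                    pl = _lowconf_pl(rng)
                else:
                    pl = _variant_pl(rng)
                calls.append(CallRecord(patient_id, pos, v.ref, v.alt, pl, platform))
            elif rng.random() < spec.ref_emit_prob:
                calls.append(
                    CallRecord(patient_id, pos, v.ref, v.alt, _ref_pl(rng), platform)
                )
        else:
            q = v.af
            g = rng.random()
            if g < q * q:
                calls.append(
                    CallRecord(patient_id, pos, v.ref, v.alt, _variant_pl(rng), platform)
                )
            elif g < q * q + 2 * q * (1 - q):
                calls.append(
                    CallRecord(patient_id, pos, v.ref, v.alt, _het_pl(rng), platform)
                )
            elif rng.random() < spec.ref_emit_prob:
                calls.append(
                    CallRecord(patient_id, pos, v.ref, v.alt, _ref_pl(rng), platform)
                )

    # private variants, unique to this patient (not in the population pool)
    n_private = rng.poisson(0.1 * spec.variant_rate * L)
    pool_positions = {v.position for v in pool}
    for _ in range(n_private):
        pos = int(rng.integers(1, L + 1))
        if pos in pool_positions:
            continue
        ref = region.base(pos)
        alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
        inside = deletion is not None and deletion.contains(pos)
        if inside:
            true_positions.add(pos)
            if rng.random() < artifact_rate:
                pl = _het_pl(rng)
            else:
                pl = _variant_pl(rng)
        else:
            pl = _het_pl(rng)
        calls.append(CallRecord(patient_id, pos, ref, alt, pl, platform))

    calls.sort(key=lambda c: c.position)
    truth = TruthEntry(
        patient=patient_id,
        platform=platform,
        deletion_class=class_draw,
        interval=deletion,
        variant_positions=frozenset(true_positions),
    )
    return Patient(patient_id, platform, depth, calls, truth)


def simulate_cohort(
    spec: CohortSpec, class_sequence: Optional[Sequence[str]] = None
) -> Cohort:
    """Simulate the full cohort.

    ``class_sequence`` overrides the random class draw with an explicit
    per-patient class list (e.g. a balanced recovery panel).
    """
    spec.validate()
    region, pool, hard_blocks = simulate_region(spec)
    ss = np.random.SeedSequence([spec.seed, 202])
    rng = np.random.default_rng(ss)

    classes = list(spec.deletion_class_probs)
    probs = np.array([spec.deletion_class_probs[c] for c in classes])
    plat_names = list(spec.platform_labels)
    plat_probs = np.array([spec.platform_labels[p].prob for p in plat_names])
    plat_probs = plat_probs / plat_probs.sum()

    patients = []
    child_seeds = ss.spawn(spec.n_patients)
    for i in range(spec.n_patients):
        if class_sequence is not None:
            class_draw = class_sequence[i]
        else:
            class_draw = classes[int(rng.choice(len(classes), p=probs))]
        platform = plat_names[int(rng.choice(len(plat_names), p=plat_probs))]
        prng = np.random.default_rng(child_seeds[i])
        patients.append(
            simulate_patient(
                spec, region, pool, hard_blocks,
                class_draw, f"P{i:03d}", platform, prng,
            )
        )
    truth = TruthSet(
        entries={p.patient_id: p.truth for p in patients},
        gene_density_multipliers=dict(spec.gene_density_multipliers),
    )
    return Cohort(spec, region, pool, patients, truth)


# ---------------------------------------------------------------------------
# Fixture output
# ---------------------------------------------------------------------------


def write_fixtures(cohort: Cohort, outdir: str | Path) -> dict:
    """Write the cohort to disk: per-patient VCF + depth TSV, region tracks,
    and a YAML manifest with platform labels and the generating seed."""
    from .vcfio import write_patient_vcf  # local import: pysam is heavier

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    region = cohort.region

    write_bed(
        outdir / "lcrs.bed",
        [iv for _, iv in region.lcr_map.lcrs],
        names=region.lcr_map.names,
    )
    write_bed(outdir / "segdups.bed", region.segdups.intervals)
    write_gene_table(outdir / "genes.tsv", region.genes)
    with open(outdir / "conservation.tsv", "w") as fh:
        track = region.conservation
        for i, s in enumerate(track.scores):
            fh.write(f"{track.start + i}\t{s:.6f}\n")
    with open(outdir / "known_variants.tsv", "w") as fh:
        fh.write("pos\tref\talt\taf\n")
        for (pos, ref, alt), af in sorted(region.known_variants.records.items()):
            fh.write(f"{pos}\t{ref}\t{alt}\t{af:.6f}\n")

    manifest: dict = {
        "seed": cohort.spec.seed,
        "n_patients": cohort.spec.n_patients,
        "contig": region.contig,
        "region_length": cohort.spec.region_length,
        "patients": [],
    }
    for p in cohort.patients:
        vcf_path = outdir / f"{p.patient_id}.vcf"
        depth_path = outdir / f"{p.patient_id}.depth.tsv"
        write_patient_vcf(vcf_path, p.calls, region)
        with open(depth_path, "w") as fh:
            for i, d in enumerate(p.depth):
                fh.write(f"{region.contig}\t{i + 1}\t{int(d)}\n")
        manifest["patients"].append(
            {
                "id": p.patient_id,
                "platform": p.platform,
                "vcf": vcf_path.name,
                "depth": depth_path.name,
                "true_class": p.truth.deletion_class,
            }
        )
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


# ---------------------------------------------------------------------------
# Direct burden-point simulation (for regression calibration studies)
# ---------------------------------------------------------------------------


def simulate_burden_points(
    rng: np.random.Generator,
    n_units: int = 40,
    mean_length: float = 3_000.0,
    rate_per_bp: float = 0.02,
    zero_density_unit: bool = False,
) -> "pd.DataFrame":
    """Draw per-unit (gene) sequenceable lengths and Poisson variant counts.

    ``rate_per_bp`` is the cohort-aggregate catalog density: with ~100
    patients and a per-patient density of ~5.8e-4/bp, the union catalog
    approaches the population-pool density (~2e-2 unique positions per
    sequenceable bp in gene-sized units). If ``zero_density_unit`` is
    true, the unit with the largest length in the upper quartile gets a
    true density of zero, emulating a variation-intolerant gene.
    """
    import pandas as pd

    lengths = rng.uniform(0.3 * mean_length, 1.9 * mean_length, n_units)
    counts = rng.poisson(rate_per_bp * lengths).astype(float)
    names = [f"U{i:03d}" for i in range(n_units)]
    zero_unit = None
    if zero_density_unit:
        q75 = np.quantile(lengths, 0.75)
        upper = np.where(lengths >= q75)[0]
        zero_idx = int(upper[np.argmax(lengths[upper])])
        counts[zero_idx] = 0.0
        zero_unit = names[zero_idx]
    df = pd.DataFrame(
        {"unit": names, "sequenceable_length": lengths, "variant_count": counts}
    )
    df.attrs["zero_density_unit"] = zero_unit
    return df
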