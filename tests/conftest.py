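import numpy as np
import pytest

from hemivar.regions import (
    ConservationTrack,
    GeneModel,
    GenomeInterval,
    KnownVariantTable,
    LCRMap,
    RegionModel,
    SegDupMask,
)
from hemivar.simulate import CohortSpec, simulate_region


@pytest.fixture(scope="session")
def default_spec() -> CohortSpec:
    return CohortSpec(seed=11)


@pytest.fixture(scope="session")
def sim_region(default_spec):
    """Default synthetic region, pool and hard blocks (seeded)."""
    return simulate_region(default_spec)


def make_tiny_region(sequence: str | None = None) -> RegionModel:
    """Hand-built 10 kb region with two genes for unit tests.

    GPLUS (+): exons [1001-1300] and [2001-2300]; coding [1101-1300] and
    [2001-2199]. GMINUS (-): single exon [5001-5300], coding [5101-5199].
    LCRs are four 200-bp blocks; one segdup at [8001-8200].
    """
    contig = "chrT"
    gplus = GeneModel(
        "GPLUS",
        "+",
        exons=[GenomeInterval(contig, 1001, 1300), GenomeInterval(contig, 2001, 2300)],
        coding=[GenomeInterval(contig, 1101, 1300), GenomeInterval(contig, 2001, 2199)],
    )
    gminus = GeneModel(
        "GMINUS",
        "-",
        exons=[GenomeInterval(contig, 5001, 5300)],
        coding=[GenomeInterval(contig, 5101, 5199)],
    )
    lcrs = LCRMap(
        [
            (n, GenomeInterval(contig, s, s + 199))
            for n, s in zip("ABCD", (3001, 4001, 6001, 7001))
        ],
        breakpoint_tolerance_bp=50,
    )
    seq = np.frombuffer(b"A" * 10_000, dtype=np.uint8).copy()
    if sequence is not None:
        raw = sequence.encode()
        seq[: len(raw)] = np.frombuffer(raw, dtype=np.uint8)
    rng = np.random.default_rng(0)
    return RegionModel(
        contig=contig,
        span=GenomeInterval(contig, 1, 10_000),
        lcr_map=lcrs,
        genes=[gplus, gminus],
        segdups=SegDupMask([GenomeInterval(contig, 8001, 8200)]),
        conservation=ConservationTrack(1, rng.normal(0, 1, 10_000)),
        known_variants=KnownVariantTable({}),
        sequence=seq,
    )


@pytest.fixture()
def tiny_region() -> RegionModel:
    return make_tiny_region()
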