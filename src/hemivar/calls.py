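"""Phred-scaled genotype-likelihood call taxonomy and hemizygous filtering.

A GATK-style caller run in emit-all-sites mode produces a record at every
position with a PL triple: Phred-scaled likelihoods for (hom-ref, het,
hom-alt), normalized so the best genotype has PL 0. In a hemizygous
deletion only one allele remains, so true variant calls there should look
homozygous-alt; heterozygous calls inside the deletion are mosaicism or
artifact and are removed.

The classification thresholds everything at ``threshold`` Phred units
(default 70): PL > 70 means the alternative genotype is >1e7-fold less
likely than the best one.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

from .regions import GenomeInterval, SegDupMask, in_mask

__all__ = [
    "PLTriple",
    "CallRecord",
    "CallClass",
    "RemovalReason",
    "FilterResult",
    "classify_call",
    "passes_hemizygous_keep",
    "filter_call_set",
]

DEFAULT_PL_THRESHOLD = 70.0


class PLTriple(NamedTuple):
    """Normalized Phred-scaled genotype likelihoods (hom-ref, het, hom-alt)."""

    ref: float
    het: float
    alt: float

    def validate(self) -> None:
        vals = (self.ref, self.het, self.alt)
        if any(v < 0 or v != v or v == float("inf") for v in vals):
            raise ValueError(f"PL values must be finite and non-negative: {self}")
        if min(vals) != 0:
            raise ValueError(f"PL triple not normalized (min must be 0): {self}")


class CallClass(enum.Enum):
    CONFIDENT_HOM_ALT = "confident_hom_alt"
    LOW_CONF_HOM_ALT = "low_conf_hom_alt"
    CONFIDENT_HET = "confident_het"
    LOW_CONF_HET = "low_conf_het"
    LIKELY_REFERENCE = "likely_reference"
    INDETERMINABLE = "indeterminable"
    UNCLASSIFIED = "unclassified"


#: Classes counting as variant (non-reference) calls.
VARIANT_CLASSES = frozenset(
    {
        CallClass.CONFIDENT_HOM_ALT,
        CallClass.LOW_CONF_HOM_ALT,
        CallClass.CONFIDENT_HET,
        CallClass.LOW_CONF_HET,
    }
)

HET_CLASSES = frozenset({CallClass.CONFIDENT_HET, CallClass.LOW_CONF_HET})
HOM_ALT_CLASSES = frozenset({CallClass.CONFIDENT_HOM_ALT, CallClass.LOW_CONF_HOM_ALT})


@dataclass
class CallRecord:
    """One emitted call for one patient at one position."""

    patient: str
    position: int
    ref: str
    alt: str
    pl: PLTriple
    platform: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")


def classify_call(
    pl: PLTriple, threshold: float = DEFAULT_PL_THRESHOLD
) -> CallClass:
    """Assign a single call class to a normalized PL triple.

    Rules, checked in order:

    1. all three likelihoods <= threshold -> indeterminable
    2. alt == 0, ref > thr, het > thr    -> confident_hom_alt
    3. alt == 0, het <= thr              -> low_conf_hom_alt
    4. het == 0, ref > thr, alt > thr    -> confident_het
    5. het == 0, ref <= thr or alt <= thr-> low_conf_het
    6. ref == 0, alt > thr               -> likely_reference
    7. anything else                     -> unclassified
    """
    pl.validate()
    thr = threshold
    if pl.ref <= thr and pl.het <= thr and pl.alt <= thr:
        return CallClass.INDETERMINABLE
    if pl.alt == 0:
        if pl.ref > thr and pl.het > thr:
            return CallClass.CONFIDENT_HOM_ALT
        if pl.het <= thr:
            return CallClass.LOW_CONF_HOM_ALT
    if pl.het == 0:
        if pl.ref > thr and pl.alt > thr:
            return CallClass.CONFIDENT_HET
        if pl.ref <= thr or pl.alt <= thr:
            return CallClass.LOW_CONF_HET
    if pl.ref == 0 and pl.alt > thr:
        return CallClass.LIKELY_REFERENCE
    return CallClass.UNCLASSIFIED


def passes_hemizygous_keep(
    pl: PLTriple, threshold: float = DEFAULT_PL_THRESHOLD
) -> bool:
    """Keep rule for calls inside the hemizygous deletion.

    A call is kept iff its hom-alt likelihood is exactly zero and the
    hom-ref likelihood exceeds the threshold. The het likelihood is not
    consulted, so a kept call may still be only moderately separated from
    the heterozygous genotype.
    """
    pl.validate()
    return pl.alt == 0 and pl.ref > threshold


class RemovalReason(enum.Enum):
    SEGDUP = "segdup"
    LIKELY_REFERENCE = "likely_reference"
    INDETERMINABLE = "indeterminable"
    FAILS_HEMIZYGOUS_KEEP = "fails_hemizygous_keep"


@dataclass
class FilterResult:
    kept: list[CallRecord]
    removed: list[tuple[CallRecord, RemovalReason]]


def filter_call_set(
    calls: Sequence[CallRecord],
    mask: SegDupMask,
    deletion: Optional[GenomeInterval] = None,
    threshold: float = DEFAULT_PL_THRESHOLD,
) -> FilterResult:
    """Filter one patient's call set.

    Removal reasons are checked in order: segmental-duplication mask, then
    likely-reference, then indeterminable, and finally — only for calls
    inside the given deletion interval — failure of the hemizygous keep
    rule. Each removed call carries the first applicable reason; kept and
    removed partition the input exactly.
    """
    kept: list[CallRecord] = []
    removed: list[tuple[CallRecord, RemovalReason]] = []
    for call in calls:
        if in_mask(call.position, mask):
            removed.append((call, RemovalReason.SEGDUP))
            continue
        cls = classify_call(call.pl, threshold)
        if cls is CallClass.LIKELY_REFERENCE:
            removed.append((call, RemovalReason.LIKELY_REFERENCE))
            continue
        if cls is CallClass.INDETERMINABLE:
            removed.append((call, RemovalReason.INDETERMINABLE))
            continue
        if deletion is not None and deletion.contains(call.position):
            if not passes_hemizygous_keep(call.pl, threshold):
                removed.append((call, RemovalReason.FAILS_HEMIZYGOUS_KEEP))
                continue
        kept.append(call)
    return FilterResult(kept=kept, removed=removed)
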