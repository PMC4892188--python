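"""VCF input/output for per-patient call sets (pysam-backed).

Each patient's calls are stored as a single-sample VCF 4.2 with GT:PL in
FORMAT; PL triples follow the VCF ordering for biallelic sites
(hom-ref, het, hom-alt).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pysam

from .calls import CallRecord, PLTriple
from .regions import RegionModel

__all__ = ["write_patient_vcf", "read_patient_vcf"]


def _genotype_from_pl(pl: PLTriple) -> tuple:
    best = min(((pl.ref, (0, 0)), (pl.het, (0, 1)), (pl.alt, (1, 1))))
    return best[1]


def write_patient_vcf(
    path: str | Path, calls: list[CallRecord], region: RegionModel
) -> None:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add(region.contig, length=region.span.end)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add(
        "PL", "G", "Integer", "Phred-scaled genotype likelihoods"
    )
    header.add_line("##source=hemivar-synthetic")
    sample = calls[0].patient if calls else "SAMPLE"
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for c in calls:
            rec = vf.new_record(
                contig=region.contig,
                start=c.position - 1,
                stop=c.position - 1 + len(c.ref),
                alleles=(c.ref, c.alt),
            )
            rec.samples[sample]["GT"] = _genotype_from_pl(c.pl)
            rec.samples[sample]["PL"] = (
                int(round(c.pl.ref)),
                int(round(c.pl.het)),
                int(round(c.pl.alt)),
            )
            vf.write(rec)


def read_patient_vcf(
    path: str | Path, patient: Optional[str] = None, platform: str = ""
) -> list[CallRecord]:
    """Read a single-sample VCF into CallRecords.

    Multi-allelic records are decomposed to the best alt allele (the one
    whose hom-alt PL is lowest), using the diagonal PL entries of the
    biallelic sub-genotypes; the retained triple is re-normalized to min 0.
    """
    calls: list[CallRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample column")
        sample = patient if patient in samples else samples[0]
        pid = patient or sample
        for rec in vf:
            fmt = rec.samples[sample]
            pl = fmt.get("PL")
            if pl is None:
                continue
            alts = rec.alts or ()
            if not alts:
                continue
            if len(alts) == 1:
                triple = (pl[0], pl[1], pl[2])
                alt = alts[0]
            else:
                # PL index of genotype (j,k), j<=k: k(k+1)/2 + j
                best_i, best_alt, best_triple = None, None, None
                for i, alt_allele in enumerate(alts, start=1):
                    het_idx = i * (i + 1) // 2
                    hom_idx = i * (i + 1) // 2 + i
                    triple_i = (pl[0], pl[het_idx], pl[hom_idx])
                    if best_triple is None or triple_i[2] < best_triple[2]:
                        best_triple, best_alt = triple_i, alt_allele
                triple, alt = best_triple, best_alt
            lo = min(triple)
            norm = PLTriple(
                float(triple[0] - lo), float(triple[1] - lo), float(triple[2] - lo)
            )
            calls.append(
                CallRecord(pid, rec.pos, rec.ref, alt, norm, platform)
            )
    return calls
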