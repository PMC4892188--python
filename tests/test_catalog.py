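"""Cohort catalog: aggregation, coding effects, rare rule, summaries."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from hemivar import data_path
from hemivar.calls import CallRecord, PLTriple
from hemivar.catalog import (
    CatalogEntry,
    build_catalog,
    classify_coding_effect,
    flag_rare,
    gene_variant_matrix,
    load_gene_variant_table,
    matrix_rollups,
    percentage,
    round_half_up,
    summarize_catalog,
)
from hemivar.deletions import DeletionCall
from hemivar.regions import GenomeInterval, KnownVariantTable

from conftest import make_tiny_region

PL = PLTriple(120.0, 90.0, 0.0)


def _dc(pid, start, end):
    return DeletionCall(pid, GenomeInterval("chrT", start, end), "AD")


class TestBuildCatalog:
    def test_shared_position_pools_carriers(self, tiny_region):
        kept = {
            "P1": [CallRecord("P1", 4500, "A", "T", PL)],
            "P2": [CallRecord("P2", 4500, "A", "T", PL)],
        }
        dels = {"P1": _dc("P1", 4000, 5000), "P2": _dc("P2", 4000, 5000)}
        cat = build_catalog(kept, dels, tiny_region)
        assert len(cat) == 1
        assert cat[0].carriers == {"P1", "P2"}
        assert cat[0].spanning == 2 and cat[0].cohort_freq == 1.0

    def test_spanning_counts_only_covering_deletions(self, tiny_region):
        kept = {"P1": [CallRecord("P1", 4500, "A", "T", PL)], "P2": []}
        dels = {"P1": _dc("P1", 4000, 5000), "P2": _dc("P2", 6000, 7000)}
        cat = build_catalog(kept, dels, tiny_region)
        assert cat[0].spanning == 1

    def test_kept_call_outside_deletion_is_hard_error(self, tiny_region):
        kept = {"P1": [CallRecord("P1", 9000, "A", "T", PL)]}
        dels = {"P1": _dc("P1", 4000, 5000)}
        with pytest.raises(ValueError, match="outside"):
            build_catalog(kept, dels, tiny_region)

    def test_empty_input_empty_catalog(self, tiny_region):
        assert build_catalog({}, {}, tiny_region) == []


def _entry(pos, ref, alt, category="coding_exonic", pop=None, carriers=1, spanning=100):
    return CatalogEntry(
        position=pos,
        ref=ref,
        alt=alt,
        carriers={f"P{i}" for i in range(carriers)},
        spanning=spanning,
        population_freq=pop,
        annotated=pop is not None,
        category=category,
    )


class TestCodingEffect:
    """The single-codon path is checked against full-CDS translation."""

    # GPLUS coding: [1101-1300]+[2001-2199]; GMINUS coding: [5101-5199]
    def _region_with(self, seq_parts):
        seq = ["A"] * 10_000
        for start, text in seq_parts:
            for i, b in enumerate(text):
                seq[start - 1 + i] = b
        return make_tiny_region("".join(seq))

    def _oracle(self, region, gene_name, pos, alt):
        gene = next(g for g in region.genes if g.name == gene_name)
        bases = []
        for civ in gene.coding:
            for p in range(civ.start, civ.end + 1):
                bases.append(alt if p == pos else region.base(p))
        cds = "".join(bases)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return str(Seq(cds).translate())

    @pytest.mark.parametrize(
        "pos,ref_codon,alt,expected",
        [
            (1103, "GAA", "G", "synonymous"),  # GAA->GAG, both Glu
            (1102, "GAA", "G", "non_synonymous"),  # GAA->GGA, Glu->Gly
            (1106, "TAC", "A", "stop_gain"),  # TAC->TAA at codon 2 pos 3
        ],
    )
    def test_plus_strand_snvs(self, pos, ref_codon, alt, expected):
        region = self._region_with([(1101, "GAATAC"), (2001, "GGT" * 66 + "G")])
        entry = _entry(pos, region.base(pos), alt)
        effect = classify_coding_effect(entry, region.genes, region)
        assert effect == expected
        # independent check: translate the whole CDS with and without the variant
        aa_ref = self._oracle(region, "GPLUS", pos, region.base(pos))
        aa_alt = self._oracle(region, "GPLUS", pos, alt)
        if expected == "synonymous":
            assert aa_ref == aa_alt
        elif expected == "stop_gain":
            assert "*" in aa_alt and aa_alt != aa_ref

    def test_minus_strand_agrees_with_full_cds_translation(self):
        rng = np.random.default_rng(9)
        cds_seq = "".join(rng.choice(list("ACGT"), 99))
        region = self._region_with([(5101, cds_seq)])
        for pos in (5105, 5150, 5199):
            ref = region.base(pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                effect = classify_coding_effect(
                    _entry(pos, ref, alt), region.genes, region
                )
                aa_ref = self._oracle(region, "GMINUS", pos, ref)
                aa_alt = self._oracle(region, "GMINUS", pos, alt)
                if aa_ref == aa_alt:
                    assert effect == "synonymous"
                elif "*" in aa_alt and "*" not in aa_ref:
                    assert effect == "stop_gain"
                else:
                    assert effect == "non_synonymous"

    def test_insertion_frameshift_by_length_mod_3(self, tiny_region):
        fs = classify_coding_effect(_entry(1150, "A", "ATT"), tiny_region.genes, tiny_region)
        assert fs == "frameshift_insertion"
        inframe = classify_coding_effect(
            _entry(1150, "A", "ATTG"), tiny_region.genes, tiny_region
        )
        assert inframe == "other"

    def test_non_coding_positions(self, tiny_region):
        assert (
            classify_coding_effect(
                _entry(4500, "A", "T", category="intergenic"), tiny_region.genes, tiny_region
            )
            == "not_coding"
        )


class TestRareRule:
    @pytest.mark.parametrize(
        "pop,carriers,spanning,expected",
        [
            (0.04, 2, 100, True),
            (0.20, 1, 100, False),  # common in the population
            (None, 5, 100, True),  # unannotated counts as rare, 5% inclusive
            (0.05, 5, 100, True),  # both boundaries inclusive
            (0.04, 6, 100, False),  # too frequent in the cohort
        ],
    )
    def test_rule_table(self, pop, carriers, spanning, expected):
        e = _entry(100, "A", "T", pop=pop, carriers=carriers, spanning=spanning)
        assert flag_rare(e) is expected

    @given(
        st.floats(0, 1),
        st.integers(0, 50),
        st.floats(0, 0.5),
        st.floats(0, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_threshold(self, pop, carriers, t1, t2):
        lo, hi = sorted((t1, t2))
        e = _entry(100, "A", "T", pop=pop, carriers=carriers, spanning=50)
        if flag_rare(e, lo):
            assert flag_rare(e, hi)


class TestPercentages:
    @pytest.mark.parametrize(
        "n,d,decimals,expected",
        [
            (9_990, 11_913, 0, 84),
            (10_493, 18_153, 1, 57.8),
            (199, 11_913, 1, 1.7),
            (88, 199, 0, 44),
            (95, 199, 0, 48),
        ],
    )
    def test_reported_precision(self, n, d, decimals, expected):
        assert percentage(n, d, decimals) == expected

    def test_zero_denominator_is_missing(self):
        assert percentage(5, 0) is None

    def test_half_up_rounding(self):
        assert round_half_up(0.5) == 1.0
        assert round_half_up(83.5, 0) == 84.0
        assert round_half_up(1.65, 1) == 1.7


class TestGeneMatrix:
    def _catalog(self):
        entries = [
            _entry(1150, "A", "T"),
            _entry(1160, "A", "T"),
            _entry(2100, "A", "T"),
        ]
        effects = ["non_synonymous", "stop_gain", "non_synonymous"]
        rare = [True, False, False]
        for e, eff, r in zip(entries, effects, rare):
            e.gene = "GPLUS"
            e.coding_effect = eff
            e.rare = r
        return entries

    def test_counts_match_brute_force_recount(self, tiny_region):
        cat = self._catalog()
        df = gene_variant_matrix(cat, tiny_region.genes)
        assert df.loc["GPLUS", "non_synonymous_total"] == 2
        assert df.loc["GPLUS", "non_synonymous_rare"] == 1
        assert df.loc["GPLUS", "stop_gain_total"] == 1
        roll = matrix_rollups(df)
        assert roll["genes_protein_altering"] == 1
        assert roll["genes_rare_protein_altering"] == 1

    def test_no_coding_variants_empty_matrix(self, tiny_region):
        df = gene_variant_matrix(
            [_entry(4500, "A", "T", category="intergenic")], tiny_region.genes
        )
        assert len(df) == 0
        assert matrix_rollups(df)["genes_protein_altering"] == 0

    def test_packaged_cohort_table_loads(self):
        df = load_gene_variant_table(data_path("cohort_gene_variants.tsv"))
        assert df.index.is_unique
        # only genes with at least one protein-altering variant remain
        assert (df[["stop_gain_total", "frameshift_insertion_total", "non_synonymous_total"]].sum(axis=1) > 0).all()


class TestSummary:
    def test_partition_identities(self, tiny_region):
        entries = [
            _entry(1150, "A", "T"),
            _entry(1050, "A", "T", category="noncoding_exonic"),
            _entry(1500, "A", "T", category="intronic"),
            _entry(4500, "A", "T", category="intergenic"),
        ]
        entries[0].coding_effect = "synonymous"
        s = summarize_catalog(entries)
        assert sum(s.by_category.values()) == s.total == 4
        assert sum(s.by_coding_effect.values()) == s.by_category["coding_exonic"]

    def test_per_class_means(self):
        entries = [_entry(100, "A", "T", carriers=2, spanning=2)]
        dels = {
            "P0": DeletionCall("P0", GenomeInterval("c", 50, 150), "AD"),
            "P1": DeletionCall("P1", GenomeInterval("c", 50, 150), "AD"),
            "P2": DeletionCall("P2", None, "none"),
        }
        s = summarize_catalog(entries, dels)
        assert s.mean_variants_per_patient_by_class == {"AD": 1.0}
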