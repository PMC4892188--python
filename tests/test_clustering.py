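"""Platform clustering: p-distance, UPGMA, cut purity, serialization."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from hemivar.calls import CallRecord, PLTriple
from hemivar.clustering import (
    ClusterNode,
    DistanceMatrix,
    PseudoSequence,
    build_pseudosequences,
    cut_tree,
    distance_matrix,
    pdistance_pairwise_deletion,
    platform_segregation_score,
    to_newick,
    upgma,
    write_phylip,
)


def _seq(pid, symbols, platform="x"):
    return PseudoSequence(pid, platform, symbols)


class TestPseudoSequences:
    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError, match="symbols"):
            PseudoSequence("P", "x", "RVX")

    def test_symbols_from_calls(self):
        pl_ref = PLTriple(0.0, 95.0, 140.0)
        pl_var = PLTriple(120.0, 90.0, 0.0)
        pl_het = PLTriple(90.0, 0.0, 120.0)
        calls = {
            "P1": [
                CallRecord("P1", 10, "A", "T", pl_var, "nimblegen"),
                CallRecord("P1", 20, "A", "T", pl_ref, "nimblegen"),
            ],
            "P2": [CallRecord("P2", 20, "A", "T", pl_het, "agilent")],
        }
        kept = {"P1": {10}}
        seqs = build_pseudosequences(calls, kept, [10, 20, 30])
        by = {s.patient: s for s in seqs}
        assert by["P1"].symbols == "VRN"
        assert by["P2"].symbols == "NNN"  # het and never-emitted are both N
        assert by["P1"].platform == "nimblegen"

    def test_platform_override_mapping(self):
        calls = {"P1": [CallRecord("P1", 10, "A", "T", PLTriple(120.0, 90.0, 0.0))]}
        seqs = build_pseudosequences(
            calls, {"P1": {10}}, [10], platforms={"P1": "agilent"}
        )
        assert seqs[0].platform == "agilent"


class TestPDistance:
    def test_hand_example(self):
        # comparable sites: 1,2,4 (site 3 has an N); one mismatch
        d, n = pdistance_pairwise_deletion(_seq("a", "RVNR"), _seq("b", "RRRR"))
        assert n == 3 and d == pytest.approx(1 / 3)

    def test_identical_sequences_distance_zero(self):
        d, n = pdistance_pairwise_deletion(_seq("a", "RVRV"), _seq("b", "RVRV"))
        assert d == 0.0 and n == 4

    def test_no_comparable_sites_is_missing(self):
        d, n = pdistance_pairwise_deletion(_seq("a", "NNRR"), _seq("b", "RVNN"))
        assert d is None and n == 0

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="length"):
            pdistance_pairwise_deletion(_seq("a", "RV"), _seq("b", "RVR"))

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s1 = "".join(rng.choice(list("RVN"), 30))
            s2 = "".join(rng.choice(list("RVN"), 30))
            assert pdistance_pairwise_deletion(
                _seq("a", s1), _seq("b", s2)
            ) == pdistance_pairwise_deletion(_seq("b", s2), _seq("a", s1))


def _dmat(labels, d):
    d = np.asarray(d, float)
    return DistanceMatrix(list(labels), d, np.full_like(d, 10, dtype=int))


def _internal_nodes(root):
    out = []
    stack = [root]
    while stack:
        n = stack.pop()
        if not n.is_leaf:
            out.append(n)
            stack.extend(n.children)
    return out


def _brute_upgma(labels, d):
    """Independent UPGMA: cluster distance recomputed as the plain mean
    over all cross-cluster leaf pairs of the original matrix. Same
    tie-break as the implementation (smallest member label pair).
    Returns {frozenset(leaves): height} for every internal node."""
    d = np.asarray(d, float)
    clusters = [({i}, labels[i]) for i in range(len(labels))]
    joined = {}
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ia, ib = clusters[a][0], clusters[b][0]
                dist = np.mean([d[i, j] for i in ia for j in ib])
                key = tuple(sorted((clusters[a][1], clusters[b][1])))
                cand = (dist, key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dist, _, a, b = best
        members = clusters[a][0] | clusters[b][0]
        joined[frozenset(labels[i] for i in members)] = dist / 2.0
        merged = (members, min(clusters[a][1], clusters[b][1]))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return joined


class TestUPGMA:
    def test_three_taxon_hand_oracle(self):
        # d(a,b)=2, d(a,c)=6, d(b,c)=8 -> join (a,b) at height 1,
        # then {a,b} to c at mean(6,8)/2 = 3.5
        root = upgma(_dmat("abc", [[0, 2, 6], [2, 0, 8], [6, 8, 0]]))
        assert root.height == pytest.approx(3.5)
        inner = next(c for c in root.children if not c.is_leaf)
        assert sorted(inner.leaves()) == ["a", "b"]
        assert inner.height == pytest.approx(1.0)

    def test_two_taxon(self):
        root = upgma(_dmat("ab", [[0, 4], [4, 0]]))
        assert root.height == pytest.approx(2.0)
        assert sorted(root.leaves()) == ["a", "b"]

    def test_single_taxon_is_leaf(self):
        root = upgma(_dmat("a", [[0.0]]))
        assert root.is_leaf and root.label == "a"

    def test_size_weighted_update_four_taxa(self):
        # after (a,b) join, d({ab},c) must be (d_ac+d_bc)/2 = 5, not
        # min/max; with d({ab},d)=9 and d(c,d)=4, (c,d) joins next.
        d = [
            [0, 2, 4, 10],
            [2, 0, 6, 8],
            [4, 6, 0, 4],
            [10, 8, 4, 0],
        ]
        root = upgma(_dmat("abcd", d))
        parts = {frozenset(n.leaves()): n.height for n in _internal_nodes(root)}
        assert parts[frozenset("ab")] == pytest.approx(1.0)
        assert parts[frozenset("cd")] == pytest.approx(2.0)
        # final join: mean of the 4 cross pairs (4,10,6,8)/4 = 7 -> h=3.5
        assert parts[frozenset("abcd")] == pytest.approx(3.5)

    def test_tie_break_lexicographic(self):
        # both (x,z) and (y,z) at distance 1; smallest label pair wins
        d = [[0, 5, 1], [5, 0, 1], [1, 1, 0]]
        root = upgma(_dmat(["x", "y", "z"], d))
        first = next(c for c in root.children if not c.is_leaf)
        assert sorted(first.leaves()) == ["x", "z"]

    def test_ultrametric_and_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            m = rng.uniform(0.01, 1.0, (n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            labels = [f"T{i:02d}" for i in range(n)]
            root = upgma(_dmat(labels, d))
            # ultrametric: heights never decrease toward the root
            for node in _internal_nodes(root):
                for c in node.children:
                    assert c.height <= node.height + 1e-12
            got = {
                frozenset(nd.leaves()): nd.height for nd in _internal_nodes(root)
            }
            want = _brute_upgma(labels, d)
            assert got.keys() == want.keys()
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-12)

    def test_merge_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(4, 10))
            m = rng.uniform(0.01, 1.0, (n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            root = upgma(_dmat([f"T{i}" for i in range(n)], d))
            heights = sorted(nd.height for nd in _internal_nodes(root))
            Z = linkage(squareform(d, checks=False), method="average")
            assert np.allclose(heights, sorted(Z[:, 2] / 2.0), atol=1e-12)

    def test_missing_entry_is_hard_error(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="missing"):
            upgma(_dmat("ab", d))

    def test_distance_matrix_from_sequences(self):
        seqs = [_seq("a", "RRVV"), _seq("b", "RRRR"), _seq("c", "NNRR")]
        dm = distance_matrix(seqs)
        assert dm.d[0, 1] == pytest.approx(0.5)
        assert dm.d[0, 2] == pytest.approx(1.0) and dm.n_comparable[0, 2] == 2
        assert not dm.has_missing


class TestCutAndPurity:
    def _tree(self):
        # ((a,b),(c,d)) with inner heights 1, 2 and root 5
        ab = ClusterNode(1.0, children=[ClusterNode(0, "a"), ClusterNode(0, "b")])
        cd = ClusterNode(2.0, children=[ClusterNode(0, "c"), ClusterNode(0, "d")])
        return ClusterNode(5.0, children=[ab, cd])

    def test_cut_k2_splits_at_root(self):
        clusters = cut_tree(self._tree(), 2)
        parts = sorted(sorted(c.leaves()) for c in clusters)
        assert parts == [["a", "b"], ["c", "d"]]

    def test_cut_k3_splits_tallest_child_next(self):
        clusters = cut_tree(self._tree(), 3)
        parts = sorted(sorted(c.leaves()) for c in clusters)
        assert parts == [["a", "b"], ["c"], ["d"]]

    def test_cut_too_many_clusters_is_error(self):
        with pytest.raises(ValueError):
            cut_tree(self._tree(), 5)

    def test_perfect_segregation_scores_one(self):
        platforms = {"a": "n", "b": "n", "c": "g", "d": "g"}
        assert platform_segregation_score(self._tree(), platforms) == 1.0

    def test_mixed_clusters_score_half(self):
        platforms = {"a": "n", "b": "g", "c": "n", "d": "g"}
        assert platform_segregation_score(self._tree(), platforms) == 0.5

    def test_single_platform_is_error(self):
        platforms = {k: "n" for k in "abcd"}
        with pytest.raises(ValueError, match="two platform"):
            platform_segregation_score(self._tree(), platforms)

    def test_purity_invariant_under_distance_scaling(self):
        rng = np.random.default_rng(3)
        n = 8
        m = rng.uniform(0.01, 1.0, (n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"T{i}" for i in range(n)]
        platforms = {lab: ("n" if i % 2 else "g") for i, lab in enumerate(labels)}
        s1 = platform_segregation_score(upgma(_dmat(labels, d)), platforms)
        s2 = platform_segregation_score(upgma(_dmat(labels, d * 17.0)), platforms)
        assert s1 == pytest.approx(s2)


class TestSerialization:
    def test_newick_three_taxa(self):
        root = upgma(_dmat("abc", [[0, 2, 6], [2, 0, 8], [6, 8, 0]]))
        nwk = to_newick(root)
        assert nwk.endswith(";") and nwk.count("(") == nwk.count(")")
        for lab in "abc":
            assert f"{lab}:" in nwk
        # branch length of the (a,b) node: 3.5 - 1.0 = 2.5
        assert ":2.500000" in nwk

    def test_newick_root_to_leaf_paths_equal_height(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0.1, 1.0, (6, 6))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        root = upgma(_dmat([f"T{i}" for i in range(6)], d))

        def depths(node, acc):
            if node.is_leaf:
                return [acc]
            out = []
            for c in node.children:
                out.extend(depths(c, acc + (node.height - c.height)))
            return out

        assert np.allclose(depths(root, 0.0), root.height)

    def test_phylip_round_trip_values(self, tmp_path):
        dm = _dmat("ab", [[0, 0.25], [0.25, 0]])
        path = tmp_path / "m.phy"
        write_phylip(path, dm)
        lines = path.read_text().splitlines()
        assert lines[0] == "2"
        assert lines[1].split()[0] == "a"
        assert float(lines[1].split()[2]) == pytest.approx(0.25)
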