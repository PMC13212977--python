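"""PCN construction: separation scores, overlap, KNN relations, perturbation.

The separation score is checked exactly against an independent brute-force
oracle (explicit BFS plus direct arithmetic) on random graphs, under both
distance conventions.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import networkx as nx

import gcnpath as gp
from gcnpath.io import GeneSetCollection
from gcnpath.pcn import (
    GeneNetwork,
    build_knn_relation,
    overlap_table,
    separation_table,
    shortest_distances,
)


def path_network(*names):
    return GeneNetwork(zip(names[:-1], names[1:]))


# ---------------------------------------------------------------- oracle ----
def oracle_separation(graph: nx.Graph, a: set, b: set, convention: str):
    """Brute-force separation score: explicit BFS, direct formula arithmetic."""
    a = sorted(set(a) & set(graph.nodes))
    b = sorted(set(b) & set(graph.nodes))
    if not a or not b:
        return None

    def d(u, v):
        try:
            return nx.shortest_path_length(graph, u, v)
        except nx.NetworkXNoPath:
            return float("inf")

    if convention == "nearest":
        cross = [min(d(x, y) for y in b) for x in a] + [min(d(y, x) for x in a) for y in b]
        within_a = [min(d(x, z) for z in a if z != x) for x in a] if len(a) > 1 else []
        within_b = [min(d(y, z) for z in b if z != y) for y in b] if len(b) > 1 else []
    else:
        cross = [d(x, y) for x in a for y in b]
        within_a = [d(a[i], a[j]) for i in range(len(a)) for j in range(i + 1, len(a))]
        within_b = [d(b[i], b[j]) for i in range(len(b)) for j in range(i + 1, len(b))]
    d_ab = float(np.mean(cross))
    d_aa = float(np.mean(within_a)) if within_a else 0.0
    d_bb = float(np.mean(within_b)) if within_b else 0.0
    if not all(map(np.isfinite, (d_ab, d_aa, d_bb))):
        return None
    return d_ab - (d_aa + d_bb) / 2.0


class TestShortestDistances:
    def test_path_graph_hop_counts(self):
        net = path_network("a", "b", "c", "d")
        dist = shortest_distances(net, ["a", "d"])
        assert dist["a"]["d"] == 3
        assert dist["a"]["a"] == 0

    def test_unreachable_is_absent(self):
        net = GeneNetwork([("a", "b"), ("x", "y")])
        dist = shortest_distances(net, ["a", "x"])
        assert "x" not in dist["a"]

    def test_all_genes_absent_errors(self):
        with pytest.raises(ValueError):
            shortest_distances(path_network("a", "b"), ["zz"])


class TestSeparationScore:
    def test_path_graph_worked_example(self):
        net = path_network("a", "b", "c", "d")
        s = gp.separation_score(net, {"a", "b"}, {"c", "d"})
        assert s == pytest.approx(0.5)  # <d_AB>=1.5, <d_AA>=<d_BB>=1

    def test_identical_sets_give_minus_within(self):
        net = path_network("a", "b")
        s = gp.separation_score(net, {"a", "b"}, {"a", "b"})
        assert s == pytest.approx(-1.0)

    def test_disconnected_pair_is_missing(self):
        net = GeneNetwork([("a", "b"), ("x", "y")])
        assert gp.separation_score(net, {"a"}, {"x"}) is None

    @pytest.mark.parametrize("convention", ["nearest", "all_pairs"])
    def test_matches_brute_force_oracle_on_random_graphs(self, convention):
        rng = np.random.default_rng(2024)
        for trial in range(100):
            n = int(rng.integers(6, 51))
            g = nx.erdos_renyi_graph(n, float(rng.uniform(0.05, 0.3)), seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
            nodes = list(g.nodes)
            a = set(rng.choice(nodes, size=int(rng.integers(1, 6)), replace=False))
            b = set(rng.choice(nodes, size=int(rng.integers(1, 6)), replace=False))
            net = GeneNetwork(g.edges)
            net.graph.add_nodes_from(nodes)  # keep isolated nodes
            ours = gp.separation_score(net, a, b, convention=convention)
            ref = oracle_separation(g, a, b, convention)
            if ref is None:
                assert ours is None, f"trial {trial}: expected MISSING"
            else:
                assert ours == pytest.approx(ref, abs=1e-12), f"trial {trial}"

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        g = nx.erdos_renyi_graph(30, 0.15, seed=9)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(30)})
        net = GeneNetwork(g.edges)
        nodes = list(g.nodes)
        a = set(rng.choice(nodes, 4, replace=False))
        b = set(rng.choice(nodes, 4, replace=False))
        assert gp.separation_score(net, a, b) == gp.separation_score(net, b, a)


class TestOverlapRatio:
    def test_identity_disjoint_and_partial(self):
        assert gp.overlap_ratio({"a", "b"}, {"a", "b"}) == 1.0
        assert gp.overlap_ratio({"a"}, {"b"}) == 0.0
        assert gp.overlap_ratio({1, 2, 3}, {3, 4}) == 0.25

    def test_both_empty_errors(self):
        with pytest.raises(ValueError):
            gp.overlap_ratio(set(), set())

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        a=st.sets(st.integers(0, 30), min_size=1, max_size=15),
        b=st.sets(st.integers(0, 30), min_size=1, max_size=15),
    )
    def test_bounds_and_symmetry_for_arbitrary_sets(self, a, b):
        r = gp.overlap_ratio(a, b)
        assert 0.0 <= r <= 1.0
        assert r == gp.overlap_ratio(b, a)
        if a == b:
            assert r == 1.0

    def test_table_symmetric_with_unit_diagonal(self):
        sets = GeneSetCollection({"p": frozenset("ab"), "q": frozenset("bc"), "r": frozenset("xy")})
        tbl = overlap_table(sets)
        np.testing.assert_allclose(tbl.to_numpy(), tbl.to_numpy().T)
        np.testing.assert_allclose(np.diag(tbl.to_numpy()), 1.0)


class TestPathwayCorrelations:
    def test_worked_values(self):
        scores = pd.DataFrame(
            [[1, 2, 3], [2, 4, 6], [3, 2, 1], [1, 3, 2]],
            index=["p1", "p2", "p3", "p4"],
            columns=["s1", "s2", "s3"],
            dtype=float,
        )
        corr = gp.pathway_correlations(scores)
        assert corr.loc["p1", "p2"] == pytest.approx(1.0)
        assert corr.loc["p1", "p3"] == pytest.approx(-1.0)
        assert corr.loc["p1", "p4"] == pytest.approx(0.5)

    def test_zero_variance_pathway_missing(self):
        scores = pd.DataFrame(
            [[1, 1, 1], [1, 2, 3]], index=["flat", "p"], columns=list("abc"), dtype=float
        )
        with pytest.warns(UserWarning):
            corr = gp.pathway_correlations(scores)
        assert np.isnan(corr.loc["flat", "p"])


class TestKnnRelation:
    def _table(self, entries, ids):
        tbl = pd.DataFrame(np.nan, index=ids, columns=ids)
        for (a, b), v in entries.items():
            tbl.loc[a, b] = v
        return tbl

    def test_ascending_selection(self):
        ids = ["P1", "P2", "P3", "P4"]
        tbl = self._table({("P1", "P2"): 0.1, ("P1", "P3"): 0.5}, ids)
        edges = build_knn_relation(tbl, k=2, higher_is_closer=False)
        assert [(s, t) for s, t in edges if s == "P1"] == [("P1", "P2"), ("P1", "P3")]

    def test_overlap_fallback_fills_shortfall(self):
        ids = ["P1", "P2", "P3", "P4"]
        primary = self._table({("P1", "P2"): 0.1}, ids)
        fallback = self._table(
            {("P1", "P3"): 0.4, ("P1", "P4"): 0.2, ("P1", "P2"): 0.9}, ids
        )
        edges = build_knn_relation(primary, k=2, higher_is_closer=False, fallback=fallback)
        p1 = [(s, t) for s, t in edges if s == "P1"]
        assert p1 == [("P1", "P2"), ("P1", "P3")]  # fallback picks highest overlap

    def test_correlation_descending(self):
        ids = ["P1", "P2", "P3"]
        tbl = self._table({("P1", "P2"): 1.0, ("P1", "P3"): 0.2}, ids)
        edges = build_knn_relation(tbl, k=1, higher_is_closer=True)
        assert ("P1", "P2") in edges

    def test_too_few_candidates_warns_and_takes_all(self):
        ids = ["P1", "P2"]
        tbl = self._table({("P1", "P2"): 0.3, ("P2", "P1"): 0.3}, ids)
        with pytest.warns(UserWarning, match="candidate"):
            edges = build_knn_relation(tbl, k=5, higher_is_closer=False)
        assert set(edges) == {("P1", "P2"), ("P2", "P1")}


class TestAssembleAndDirectionality:
    def test_typed_edge_counts(self):
        order = [f"P{i}" for i in range(4)]
        e = [("P0", "P1"), ("P1", "P2")]
        pcn = gp.assemble_pcn(e, e, e, order, k=2)
        assert len(pcn.edges) == 6
        assert len(pcn.edges_of("grn")) == 2

    def test_empty_relation_warns(self):
        order = ["P0", "P1"]
        with pytest.warns(UserWarning, match="no edges"):
            pcn = gp.assemble_pcn([("P0", "P1")], [("P0", "P1")], [], order)
        assert pcn.edges_of("corr") == []

    def test_duplicates_removed_with_warning(self):
        order = ["P0", "P1"]
        with pytest.warns(UserWarning):
            pcn = gp.assemble_pcn(
                [("P0", "P1"), ("P0", "P1")], [("P0", "P1")], [("P1", "P0")], order
            )
        assert len(pcn.edges_of("ppi")) == 1

    def test_unknown_pathway_errors(self):
        with pytest.raises(ValueError):
            gp.assemble_pcn([("P0", "XX")], [], [], ["P0", "P1"])

    def test_knn_asymmetry_witness(self):
        """Three pathways where P1 -> P2 exists but P2 -> P1 does not."""
        ids = ["P1", "P2", "P3"]
        tbl = pd.DataFrame(
            [[np.nan, 0.1, 0.9], [0.1, np.nan, 0.05], [0.9, 0.05, np.nan]],
            index=ids, columns=ids,
        )
        edges = set(build_knn_relation(tbl, k=1, higher_is_closer=False))
        assert ("P1", "P2") in edges and ("P2", "P1") not in edges

    def test_out_degree_exactly_k(self, tiny_pipeline):
        pcn = tiny_pipeline["pcn"]
        for rel in ("ppi", "grn", "corr"):
            degs = pcn.out_degrees(rel)
            assert all(d == pcn.k for d in degs.values()), rel

    def test_serialization_round_trip(self, tiny_pipeline, tmp_path):
        pcn = tiny_pipeline["pcn"]
        pcn.to_files(tmp_path / "edges.tsv", tmp_path / "hdr.json")
        back = gp.PCNGraph.from_files(tmp_path / "edges.tsv", tmp_path / "hdr.json")
        assert back.pathway_ids == pcn.pathway_ids
        assert sorted(back.edges) == sorted(pcn.edges)


class TestPerturbPCN:
    def test_degree_preservation_across_seeds(self, tiny_pipeline):
        pcn = tiny_pipeline["pcn"]
        for seed in range(10):
            pert = gp.perturb_pcn(pcn, seed=seed)
            for rel in ("ppi", "grn", "corr"):
                assert pert.out_degrees(rel) == pcn.out_degrees(rel), (seed, rel)
                in_before = sorted(t for _, t in pcn.edges_of(rel))
                in_after = sorted(t for _, t in pert.edges_of(rel))
                assert in_before == in_after, (seed, rel)

    def test_deterministic_given_seed(self, tiny_pipeline):
        pcn = tiny_pipeline["pcn"]
        assert gp.perturb_pcn(pcn, seed=3).edges == gp.perturb_pcn(pcn, seed=3).edges

    def test_substantial_rewiring(self):
        rng = np.random.default_rng(1)
        ids = [f"P{i:02d}" for i in range(50)]
        edges = []
        for s in ids:
            for t in rng.choice([x for x in ids if x != s], 5, replace=False):
                edges.append((s, t))
        pcn = gp.PCNGraph(ids, [(s, t, "ppi") for s, t in edges], k=5)
        changed = []
        for seed in range(10):
            pert = gp.perturb_pcn(pcn, seed=seed)
            frac = 1 - len(set(pert.edges_of("ppi")) & set(edges)) / len(edges)
            changed.append(frac)
        assert all(f >= 0.30 for f in changed)
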