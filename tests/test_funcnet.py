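import itertools
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbdissect.funcnet import (
    build_go_network,
    cluster_modules,
    clustering_stats,
    hypergeom_enrich,
    jaccard,
    top_terms,
    topological_overlap,
)
from herbdissect.patterns import GeneModule


def module_of(genes, module_id="m1"):
    return GeneModule(module_id=module_id, code=(1, 0, 0), genes=frozenset(genes))


def hypergeom_brute(N, K, n, k):
    """Upper-tail probability by direct enumeration over the overlap."""
    return sum(
        comb(K, i) * comb(N - K, n - i) / comb(N, n)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    )


class TestEnrichment:
    def test_exact_tail_example(self):
        # N=20, K=5, n=5, k=4
        genes = [f"g{i}" for i in range(20)]
        universe = set(genes)
        module = module_of(genes[:5])
        term = set(genes[1:5]) | {genes[10]}  # overlap 4
        res = hypergeom_enrich(module, {"t": term}, universe)
        expected = hypergeom_brute(20, 5, 5, 4)
        assert np.isclose(res.loc[0, "p"], expected)

    def test_module_identical_term_minimal_p(self):
        genes = [f"g{i}" for i in range(12)]
        module = module_of(genes[:4])
        res = hypergeom_enrich(module, {"t": set(genes[:4])}, set(genes))
        assert np.isclose(res.loc[0, "p"], 1 / comb(12, 4))

    def test_disjoint_term_not_reported(self):
        genes = [f"g{i}" for i in range(10)]
        res = hypergeom_enrich(module_of(genes[:3]), {"t": set(genes[5:])}, set(genes))
        assert res.empty

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(module_of(["a"]), {"t": {"a"}}, set())

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_on_random_instances(self, data):
        N = data.draw(st.integers(4, 25))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        genes = [f"g{i}" for i in range(N)]
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        term = set(rng.choice(genes, K, replace=False))
        module_genes = set(rng.choice(genes, n, replace=False))
        k = len(term & module_genes)
        if k == 0:
            return
        res = hypergeom_enrich(module_of(module_genes), {"t": term}, set(genes))
        assert np.isclose(res.loc[0, "p"], hypergeom_brute(N, K, n, k), atol=1e-12)


class TestTopTerms:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["module_id", "term_id", "k", "K", "n", "N", "p", "padj"])

    def test_fewer_terms_than_limit(self):
        df = self._frame([("m", f"t{i}", 1, 2, 3, 10, 0.1 * i + 0.01, 0.5) for i in range(10)])
        assert len(top_terms(df, 15)) == 10

    def test_tie_break_by_k_then_id(self):
        df = self._frame(
            [("m", "tB", 2, 5, 5, 20, 0.01, 0.1), ("m", "tA", 2, 5, 5, 20, 0.01, 0.1),
             ("m", "tC", 5, 5, 5, 20, 0.01, 0.1)]
        )
        out = top_terms(df, 3)
        assert list(out["term_id"]) == ["tC", "tA", "tB"]

    def test_zero_limit(self):
        df = self._frame([("m", "t", 1, 2, 3, 10, 0.5, 0.5)])
        assert top_terms(df, 0).empty


class TestJaccard:
    def test_closed_forms(self):
        assert jaccard({"a"}, {"a"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_two_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())

    @given(
        st.sets(st.integers(0, 15), min_size=1, max_size=10),
        st.sets(st.integers(0, 15), min_size=1, max_size=10),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        j = jaccard(a, b)
        assert j == jaccard(b, a)
        assert 0 <= j <= 1


def make_network(term_sets, threshold=0.2, modules=None):
    modules = modules or {t: "m1" for t in term_sets}
    selected = {}
    for term, module_id in modules.items():
        selected.setdefault(module_id, []).append(
            {"module_id": module_id, "term_id": term, "k": 1, "K": 1, "n": 1,
             "N": 1, "p": 0.01, "padj": 0.01}
        )
    selected = {m: pd.DataFrame(rows) for m, rows in selected.items()}
    return build_go_network(selected, term_sets, threshold=threshold, dedupe=True)


class TestNetwork:
    def test_strict_threshold_boundary(self):
        # J({1..4},{4..7... }) engineered to exactly 0.2: 1 shared of 5 union
        sets = {"a": {1, 2, 3}, "b": {3, 4, 5}}  # J = 1/5 = 0.2 exactly
        net = make_network(sets, threshold=0.2)
        assert net.number_of_edges() == 0

    def test_threshold_one_only_identical(self):
        sets = {"a": {1, 2}, "b": {1, 2}, "c": {1, 2, 3}}
        net = make_network(sets, threshold=0.999999)
        assert set(map(frozenset, net.edges)) == {frozenset({"a", "b"})}

    def test_enumerated_edge_set(self):
        sets = {
            "a": {1, 2, 3, 4},
            "b": {3, 4, 5, 6},    # J(a,b) = 2/6 = 0.333
            "c": {7, 8},          # J to all others below threshold
            "d": {1, 2, 3},       # J(a,d) = 3/4; J(b,d) = 1/6
        }
        net = make_network(sets, threshold=0.2)
        expected = set()
        for u, v in itertools.combinations(sets, 2):
            if jaccard(sets[u], sets[v]) > 0.2:
                expected.add(frozenset({u, v}))
        assert set(map(frozenset, net.edges)) == expected

    def test_order_independence(self):
        rng = np.random.default_rng(2)
        sets = {f"t{i}": set(rng.choice(30, 8, replace=False)) for i in range(10)}
        net1 = make_network(sets)
        net2 = make_network(dict(reversed(list(sets.items()))))
        assert set(map(frozenset, net1.edges)) == set(map(frozenset, net2.edges))

    def test_duplicate_term_instances_share_gene_sets(self):
        sets = {"t": {1, 2, 3}}
        selected = {
            m: pd.DataFrame([{"module_id": m, "term_id": "t", "k": 1, "K": 1, "n": 1,
                              "N": 1, "p": 0.01, "padj": 0.01}])
            for m in ("m1", "m2")
        }
        net = build_go_network(selected, sets, threshold=0.2, dedupe=False)
        assert net.number_of_nodes() == 2
        assert net.get_edge_data("t@m1", "t@m2")["jaccard"] == 1.0


def brute_force_ci(g, v):
    nbrs = list(g.neighbors(v))
    k = len(nbrs)
    if k < 2:
        return 0.0
    closed = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
    return 2 * closed / (k * (k - 1))


class TestClusteringStats:
    def _with_modules(self, g, module="m1"):
        for v in g.nodes:
            g.nodes[v]["module"] = module
            g.nodes[v].setdefault("p", 0.01)
        return g

    def test_triangle_is_fully_clustered(self):
        g = self._with_modules(nx.complete_graph(3))
        stats = clustering_stats(g)
        assert (stats.node_table["Ci"] == 1.0).all()
        assert stats.module_table.loc[0, "C"] == 1.0

    def test_path_has_zero_clustering(self):
        g = self._with_modules(nx.path_graph(3))
        stats = clustering_stats(g)
        assert (stats.node_table["Ci"] == 0.0).all()

    def test_five_node_graph_matches_brute_force(self):
        g = nx.Graph([(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (2, 4)])
        g = self._with_modules(g)
        stats = clustering_stats(g)
        for _, row in stats.node_table.iterrows():
            assert np.isclose(row["Ci"], brute_force_ci(g, row["node"]))

    @given(st.integers(0, 5000))
    @settings(max_examples=200, deadline=None)
    def test_random_graphs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.9), seed=int(rng.integers(1 << 30)))
        g = self._with_modules(g)
        stats = clustering_stats(g)
        for _, row in stats.node_table.iterrows():
            assert np.isclose(row["Ci"], brute_force_ci(g, row["node"]))

    def test_extramodular_cross_degree(self):
        g = nx.Graph([("a", "b"), ("a", "x"), ("b", "y"), ("x", "y")])
        for v in "ab":
            g.nodes[v].update(module="m1", p=0.01)
        for v in "xy":
            g.nodes[v].update(module="m2", p=0.01)
        stats = clustering_stats(g)
        by_mod = stats.module_table.set_index("module")
        assert by_mod.loc["m1", "extramodular"] == 2
        assert by_mod.loc["m1", "total_degree"] == 4


def brute_force_tom(A, i, j):
    k = A.sum(axis=1)
    l_ij = sum(A[i, u] * A[u, j] for u in range(len(A)))
    denom = min(k[i], k[j]) + 1 - A[i, j]
    return (l_ij + A[i, j]) / denom if denom > 0 else 0.0


class TestTopologicalOverlap:
    def _with_modules(self, g):
        for v in g.nodes:
            g.nodes[v].update(module="m1", p=0.01)
        return g

    def test_clique_saturates(self):
        g = self._with_modules(nx.complete_graph(5))
        tom = topological_overlap(g)
        off = tom.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 1.0)  # (3 shared + 1) / (4 + 1 - 1)

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        g.add_edge(0, 1)
        g = self._with_modules(g)
        tom = topological_overlap(g)
        assert tom.loc[2, 0] == 0.0 and tom.loc[2, 2] == 1.0

    def test_hand_computed_small_graph(self):
        # square with a diagonal: 0-1, 1-2, 2-3, 3-0, 0-2
        g = self._with_modules(nx.Graph([(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)]))
        tom = topological_overlap(g)
        A = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert np.isclose(tom.iloc[i, j], brute_force_tom(A, i, j))

    @given(st.integers(0, 5000))
    @settings(max_examples=200, deadline=None)
    def test_random_graphs_match_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.9), seed=int(rng.integers(1 << 30)))
        g = self._with_modules(g)
        nodes = sorted(g.nodes)
        tom = topological_overlap(g, nodes)
        A = nx.to_numpy_array(g, nodelist=nodes)
        vals = tom.to_numpy()
        assert np.allclose(vals, vals.T)
        assert (vals >= 0).all() and (vals <= 1 + 1e-12).all()
        i, j = int(rng.integers(n)), int(rng.integers(n))
        if i != j:
            assert np.isclose(vals[i, j], brute_force_tom(A, i, j))


class TestClusterModules:
    def _planted_network(self, n_blocks=3, terms_per_module=4, genes_per_block=30):
        """Blocks of modules sharing gene pools -> dense within-block TOM."""
        term_sets, modules = {}, {}
        rng = np.random.default_rng(1)
        for b in range(n_blocks):
            pool = [f"b{b}_g{i}" for i in range(genes_per_block)]
            for m in range(2):  # two modules per block
                module_id = f"mod_b{b}_{m}"
                for t in range(terms_per_module):
                    term = f"{module_id}_t{t}"
                    term_sets[term] = set(rng.choice(pool, 12, replace=False))
                    modules[term] = module_id
        return make_network(term_sets, threshold=0.2, modules=modules)

    def test_planted_blocks_recovered(self):
        net = self._planted_network()
        tom = topological_overlap(net)
        clustering = cluster_modules(net, tom, n_clusters=3)
        blocks = {m: m.split("_")[1] for m in clustering.labels.index}
        # modules of the same block must share a cluster, distinct blocks must not
        for a in clustering.labels.index:
            for b in clustering.labels.index:
                same_cluster = clustering.labels[a] == clustering.labels[b]
                assert same_cluster == (blocks[a] == blocks[b])

    def test_singleton_clusters(self):
        net = self._planted_network(n_blocks=2)
        tom = topological_overlap(net)
        n_modules = len({net.nodes[v]["module"] for v in net.nodes})
        clustering = cluster_modules(net, tom, n_clusters=n_modules)
        assert clustering.labels.nunique() == n_modules

    def test_too_few_modules_rejected(self):
        net = self._planted_network(n_blocks=1)
        tom = topological_overlap(net)
        with pytest.raises(ValueError, match="n_clusters"):
            cluster_modules(net, tom, n_clusters=5)

    def test_dissimilarity_symmetric_zero_diagonal(self):
        net = self._planted_network()
        tom = topological_overlap(net)
        clustering = cluster_modules(net, tom, n_clusters=3)
        D = clustering.dissimilarity.to_numpy()
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)
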