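import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stagepath.io import ValidationError
from stagepath.network import (
    CoexpressionNetwork,
    build_network,
    count_edge_signs,
    degree_weights,
    topology,
)


def _frame(values, genes=None):
    arr = np.asarray(values, dtype=float)
    return pd.DataFrame(arr, index=genes or [f"g{i}" for i in range(arr.shape[0])],
                        columns=[f"s{i}" for i in range(arr.shape[1])])


def _net_from_edges(edges, nodes=None):
    G = nx.Graph()
    if nodes:
        G.add_nodes_from(nodes)
    for a, b in edges:
        G.add_edge(a, b, r=1.0, sign="positive")
    return CoexpressionNetwork(graph=G, threshold=0.5)


class TestBuildNetwork:
    def test_correlation_equal_to_threshold_draws_no_edge(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        r = float(np.corrcoef(x, y)[0, 1])
        net = build_network(_frame([x, y]), threshold=r)
        assert net.graph.number_of_edges() == 0  # strict: r == threshold excluded
        net2 = build_network(_frame([x, y]), threshold=r - 1e-9)
        assert net2.graph.number_of_edges() == 1

    def test_identical_vectors_give_positive_edge(self):
        v = np.array([1.0, 2.0, 3.0, 5.0])
        net = build_network(_frame([v, v]))
        assert net.graph.has_edge("g0", "g1")
        assert net.graph["g0"]["g1"]["sign"] == "positive"
        assert net.graph["g0"]["g1"]["r"] == pytest.approx(1.0)

    def test_anticorrelated_pair_gives_negative_edge(self):
        v = np.array([1.0, 2.0, 3.0, 5.0])
        net = build_network(_frame([v, -v]))
        assert net.graph["g0"]["g1"]["sign"] == "negative"
        assert count_edge_signs(net) == (0, 1, 1)

    def test_edge_set_matches_all_pairs_loop(self):
        rng = np.random.default_rng(13)
        frame = _frame(rng.standard_normal((30, 25)))
        net = build_network(frame, threshold=0.3)
        got = {frozenset((a, b)): d["sign"] for a, b, d in net.graph.edges(data=True)}
        expected = {}
        for i in range(30):
            for j in range(i + 1, 30):
                r, _ = sps.pearsonr(frame.iloc[i], frame.iloc[j])
                if abs(r) > 0.3:
                    expected[frozenset((f"g{i}", f"g{j}"))] = "positive" if r > 0 else "negative"
        assert got == expected

    def test_too_few_samples_errors(self):
        with pytest.raises(ValidationError):
            build_network(_frame(np.ones((3, 2))))

    def test_requested_genes_appear_even_if_isolated(self):
        rng = np.random.default_rng(1)
        frame = _frame(rng.standard_normal((5, 10)))
        net = build_network(frame, genes={"g0", "g3"}, threshold=0.99)
        assert set(net.nodes) == {"g0", "g3"}


class TestCountEdgeSigns:
    def test_empty_network(self):
        assert count_edge_signs(_net_from_edges([], nodes=["a"])) == (0, 0, 0)

    def test_positive_triangle(self):
        net = _net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        assert count_edge_signs(net) == (3, 0, 3)


class TestTopology:
    def test_three_node_path(self):
        net = _net_from_edges([("a", "b"), ("b", "c")])
        topo = topology(net)
        assert topo.average_shortest_path == pytest.approx(4 / 3)
        assert topo.closeness["b"] == pytest.approx(1.0)
        assert topo.closeness["a"] == pytest.approx(2 / 3)

    def test_triangle_fully_clustered(self):
        topo = topology(_net_from_edges([("a", "b"), ("b", "c"), ("a", "c")]))
        assert all(c == 1.0 for c in topo.clustering.values())
        assert topo.average_shortest_path == 1.0

    def test_isolated_node_gets_zeros(self):
        net = _net_from_edges([("a", "b")], nodes=["a", "b", "z"])
        topo = topology(net)
        assert topo.closeness["z"] == 0.0
        assert topo.clustering["z"] == 0.0
        assert topo.average_shortest_path == 1.0  # disconnected pairs excluded

    def test_matches_bfs_and_triple_count_oracle(self):
        rng = np.random.default_rng(23)
        for trial in range(5):
            n = int(rng.integers(10, 50))
            G = nx.gnp_random_graph(n, 0.1, seed=int(rng.integers(0, 10_000)))
            G = nx.relabel_nodes(G, {i: f"g{i}" for i in range(n)})
            nx.set_edge_attributes(G, "positive", "sign")
            topo = topology(CoexpressionNetwork(graph=G, threshold=0.5))
            # --- oracle: hand-rolled BFS distances ---
            def bfs(start):
                dist = {start: 0}
                frontier = [start]
                while frontier:
                    nxt = []
                    for u in frontier:
                        for v in G.neighbors(u):
                            if v not in dist:
                                dist[v] = dist[u] + 1
                                nxt.append(v)
                    frontier = nxt
                return dist

            total, pairs = 0, 0
            for u in G.nodes:
                dist = bfs(u)
                ds = [d for v, d in dist.items() if v != u]
                total += sum(ds)
                pairs += len(ds)
                expect_close = len(ds) / sum(ds) if ds else 0.0
                assert topo.closeness[u] == pytest.approx(expect_close, abs=1e-10)
                # clustering: closed / possible triplets
                nbrs = list(G.neighbors(u))
                k = len(nbrs)
                closed = sum(
                    1 for a in range(k) for b in range(a + 1, k) if G.has_edge(nbrs[a], nbrs[b])
                )
                expect_clust = 2 * closed / (k * (k - 1)) if k >= 2 else 0.0
                assert topo.clustering[u] == pytest.approx(expect_clust, abs=1e-10)
            expect_asp = total / pairs if pairs else 0.0
            assert topo.average_shortest_path == pytest.approx(expect_asp, abs=1e-10)


class TestDegreeWeights:
    def test_sigmoid_values(self):
        net = _net_from_edges([("a", "b"), ("a", "c")], nodes=["a", "b", "c", "iso"])
        w = degree_weights(net, {"a", "b", "c", "iso", "absent"})
        assert w["iso"] == 0.5  # degree 0
        assert w["absent"] == 0.5  # not in network at all
        assert w["a"] == pytest.approx(1 / (1 + math.exp(-2)))
        assert w["b"] == pytest.approx(1 / (1 + math.exp(-1)))

    def test_strictly_increasing_in_degree(self):
        sigmoid = lambda d: 1 / (1 + math.exp(-d))
        # strictly increasing until float saturation (exp(-d) underflows near d~37)
        values = [sigmoid(d) for d in range(31)]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert all(0.5 <= v < 1 for v in values)
        assert sigmoid(100) <= 1.0


def test_planted_block_edges_recovered(small_spec):
    """Equicorrelated rho=0.8 blocks are recovered with sensitivity >= 0.95."""
    from stagepath.simulate import SyntheticSpec, generate_cohort

    spec = SyntheticSpec(n_genes=60, n_samples_per_stage=(200, 2, 2, 2), n_pathways=2,
                         genes_per_pathway=15, n_planted_pathways=2, effect_size=0.0,
                         coexpr_block_rho=0.8, missing_rate=0.0, rng_seed=31)
    matrix, cohort, _, truth = generate_cohort(spec)
    controls = cohort.control_samples()
    net = build_network(matrix, samples=controls, threshold=0.5)
    hits, total = 0, 0
    for pw in truth.planted_pathways:
        members = [g for g, b in truth.blocks.items() if b == pw]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                total += 1
                hits += net.graph.has_edge(a, b)
    assert hits / total >= 0.95
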