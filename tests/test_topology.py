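"""Network statistics checked against hand-rolled brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from honchains import (
    DegreeRecord,
    HONGraph,
    HONNode,
    betweenness,
    build_network,
    clustering_coefficient,
    cluster_frequency_table,
    count_subpaths,
    cumulative_degree_distribution,
    degree_metrics,
    extract_rules,
    fit_degree_distribution,
    kcore_table,
    path_metrics,
    random_baseline,
)


def digraph(*edges) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_edges_from((u, v, {"weight": 1}) for u, v in edges)
    return g


def random_digraph(n: int, p: float, seed: int) -> nx.DiGraph:
    return nx.gnp_random_graph(n, p, seed=seed, directed=True)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementations under test)
# ---------------------------------------------------------------------------

def oracle_floyd_warshall(g: nx.DiGraph):
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    inf = float("inf")
    dist = [[inf] * n for _ in range(n)]
    for i in range(n):
        dist[i][i] = 0
    for u, v in g.edges:
        dist[idx[u]][idx[v]] = 1
    for k in range(n):
        for i in range(n):
            dik = dist[i][k]
            if dik == inf:
                continue
            for j in range(n):
                if dik + dist[k][j] < dist[i][j]:
                    dist[i][j] = dik + dist[k][j]
    finite = [dist[i][j] for i in range(n) for j in range(n) if i != j
              and dist[i][j] < inf]
    if not finite:
        return 0.0, 0, 0
    return sum(finite) / len(finite), max(finite), len(finite)


def oracle_clustering(g: nx.DiGraph) -> float:
    und = {n: set() for n in g.nodes}
    for u, v in g.edges:
        if u != v:
            und[u].add(v)
            und[v].add(u)
    total = 0.0
    for n, nbrs in und.items():
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(sorted(nbrs, key=str), 2)
            if b in und[a]
        )
        total += 2.0 * links / (k * (k - 1))
    return total / len(und)


def oracle_betweenness(g: nx.DiGraph) -> dict:
    """Enumerate every geodesic between every ordered pair by DFS."""
    nodes = list(g.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    sp = dict(nx.all_pairs_shortest_path_length(g))
    for s in nodes:
        for t in nodes:
            if s == t or t not in sp[s]:
                continue
            d = sp[s][t]
            paths = []
            stack = [[s]]
            while stack:
                path = stack.pop()
                last = path[-1]
                if last == t:
                    paths.append(path)
                    continue
                for nb in g.successors(last):
                    # step must stay on some geodesic from s to t
                    if (
                        sp[s].get(nb) == len(path)
                        and sp[nb].get(t) == d - len(path)
                    ):
                        stack.append(path + [nb])
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)
    scale = (n - 1) * (n - 2)
    return {v: s / scale for v, s in score.items()}


def oracle_core_numbers(g: nx.DiGraph) -> dict:
    und = {n: set() for n in g.nodes}
    for u, v in g.edges:
        if u != v:
            und[u].add(v)
            und[v].add(u)
    core = {}
    remaining = dict(und)
    k = 0
    while remaining:
        while True:
            peel = [n for n, nbrs in remaining.items() if len(nbrs) <= k]
            if not peel:
                break
            for n in peel:
                core[n] = k
                for nb in remaining[n]:
                    remaining[nb].discard(n)
                del remaining[n]
        k += 1
    return core


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

class TestDegrees:
    def test_single_edge(self):
        records, avg = degree_metrics(digraph(("a", "b")))
        by = {r.node: r for r in records}
        assert (by["a"].in_degree, by["a"].out_degree, by["a"].all_degree) == (0, 1, 1)
        assert (by["b"].in_degree, by["b"].out_degree, by["b"].all_degree) == (1, 0, 1)
        assert avg == 1.0

    def test_average_degree_243_nodes_545_edges(self):
        g = nx.gnm_random_graph(243, 545, seed=0, directed=True)
        _, avg = degree_metrics(g)
        assert round(avg, 2) == 4.49

    def test_worked_example_hon_node_degrees(self, worked_chains):
        table = count_subpaths(worked_chains, order=5)
        hon = build_network(extract_rules(worked_chains), table)
        records, _ = degree_metrics(hon)
        by = {r.node.label: r for r in records}
        assert (by["A1|H05"].in_degree, by["A1|H05"].out_degree) == (1, 1)
        assert by["A1|H05"].all_degree == 2

    def test_degree_conservation(self):
        g = random_digraph(40, 0.1, seed=5)
        records, avg = degree_metrics(g)
        assert sum(r.in_degree for r in records) == g.number_of_edges()
        assert sum(r.out_degree for r in records) == g.number_of_edges()
        assert avg == pytest.approx(2 * g.number_of_edges() / 40)

    def test_removing_top_node_never_raises_degrees(self):
        g = random_digraph(30, 0.15, seed=2)
        records, _ = degree_metrics(g)
        top = max(records, key=lambda r: r.all_degree).node
        before = {r.node: r.all_degree for r in records}
        h = g.copy()
        h.remove_node(top)
        after, _ = degree_metrics(h)
        assert all(r.all_degree <= before[r.node] for r in after)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            degree_metrics(nx.DiGraph())


class TestCumulativeDistribution:
    def _records(self, degrees):
        return [
            DegreeRecord(node=HONNode(f"H{i+1:02d}"), in_degree=d, out_degree=0)
            for i, d in enumerate(degrees)
        ]

    def test_uniform_degrees(self):
        assert cumulative_degree_distribution(self._records([2, 2, 2])) == [(2, 1.0)]

    def test_mixed_degrees(self):
        out = cumulative_degree_distribution(self._records([1, 1, 2, 4]))
        assert out == [(1, 1.0), (2, 0.5), (4, 0.25)]

    def test_non_increasing_and_starts_at_one(self):
        rng = np.random.default_rng(0)
        out = cumulative_degree_distribution(
            self._records(rng.integers(1, 12, size=10).tolist())
        )
        ps = [p for _, p in out]
        assert ps[0] == 1.0
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestDistributionFit:
    def test_exact_power_law_recovered(self):
        pts = [(k, 2.0 * k**-1.5) for k in range(1, 11)]
        fit = fit_degree_distribution(pts)
        assert fit.coefficient == pytest.approx(2.0, abs=1e-9)
        assert fit.exponent == pytest.approx(-1.5, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_power_law_exponent(self):
        rng = np.random.default_rng(1)
        pts = [
            (k, 2.0 * k**-1.5 * float(np.exp(rng.normal(0, 0.01))))
            for k in range(1, 30)
        ]
        fit = fit_degree_distribution(pts)
        assert fit.exponent == pytest.approx(-1.5, abs=0.05)

    def test_star_graph_has_too_few_distinct_degrees(self):
        # a star exposes only two distinct degrees, below the 3-point minimum
        records, _ = degree_metrics(nx.DiGraph(nx.star_graph(10)))
        with pytest.raises(ValueError):
            fit_degree_distribution(cumulative_degree_distribution(records))

    def test_fit_contract_on_arbitrary_graph(self):
        g = nx.DiGraph(nx.star_graph([f"n{i}" for i in range(11)]))
        g.add_edges_from([("x", "n1"), ("y", "n1"), ("x", "y")])
        fit = fit_degree_distribution(
            cumulative_degree_distribution(degree_metrics(g)[0])
        )
        assert 0.0 <= fit.r_squared <= 1.0

    def test_exponential_form(self):
        pts = [(k, 3.0 * float(np.exp(-0.4 * k))) for k in range(1, 11)]
        fit = fit_degree_distribution(pts, form="exponential")
        assert fit.coefficient == pytest.approx(3.0, abs=1e-9)
        assert fit.exponent == pytest.approx(-0.4, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_degree_distribution([(1, 1.0), (2, 0.5)])


class TestPathMetrics:
    def test_directed_path(self):
        pm = path_metrics(digraph(("a", "b"), ("b", "c")))
        assert pm.average_path_length == pytest.approx(4 / 3)
        assert pm.diameter == 2
        assert pm.reachable_pairs == 3

    def test_complete_digraph(self):
        g = nx.complete_graph(4, create_using=nx.DiGraph)
        pm = path_metrics(g)
        assert pm.average_path_length == 1.0
        assert pm.diameter == 1

    def test_edgeless_graph(self):
        g = nx.DiGraph()
        g.add_nodes_from("ab")
        assert path_metrics(g) == (0.0, 0, 0) or path_metrics(g).reachable_pairs == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floyd_warshall_oracle(self, seed):
        g = random_digraph(50, 0.06, seed=seed)
        pm = path_metrics(g)
        apl, dia, pairs = oracle_floyd_warshall(g)
        assert pm.average_path_length == pytest.approx(apl, abs=1e-9)
        assert pm.diameter == dia
        assert pm.reachable_pairs == pairs


class TestClustering:
    def test_triangle(self):
        assert clustering_coefficient(digraph(("a", "b"), ("b", "c"), ("c", "a"))) == 1.0

    def test_star(self):
        g = nx.DiGraph(nx.star_graph(5))
        assert clustering_coefficient(g) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triangle_counting_oracle(self, seed):
        g = random_digraph(30, 0.12, seed=seed)
        assert clustering_coefficient(g) == pytest.approx(
            oracle_clustering(g), abs=1e-9
        )


class TestBetweenness:
    def test_directed_path_midpoint(self):
        records = betweenness(digraph(("a", "b"), ("b", "c")))
        by = {r.node: r.betweenness for r in records}
        assert by["b"] == pytest.approx(0.5)
        assert by["a"] == by["c"] == 0.0

    def test_complete_digraph_all_zero(self):
        g = nx.complete_graph(5, create_using=nx.DiGraph)
        assert all(r.betweenness == 0.0 for r in betweenness(g))

    def test_values_in_unit_interval(self):
        g = random_digraph(40, 0.08, seed=9)
        assert all(0.0 <= r.betweenness <= 1.0 for r in betweenness(g))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_geodesic_enumeration_oracle(self, seed):
        g = random_digraph(40, 0.07, seed=seed)
        records = betweenness(g)
        oracle = oracle_betweenness(g)
        for r in records:
            assert r.betweenness == pytest.approx(oracle[r.node], abs=1e-9)


class TestKCore:
    def test_triangle_plus_pendant(self):
        g = digraph(("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"))
        records, table = kcore_table(g)
        by = {r.node: r.cluster_value for r in records}
        assert by == {"a": 2, "b": 2, "c": 2, "d": 1}
        rows = {row["Cluster"]: row for _, row in table.iterrows()}
        assert rows[1]["Freq"] == 1 and rows[1]["Freq%"] == 25.00
        assert rows[2]["Freq"] == 3 and rows[2]["Freq%"] == 75.00
        assert rows[2]["CumFreq"] == 4 and rows[2]["CumFreq%"] == 100.00

    def test_reference_frequency_column_arithmetic(self):
        """Cluster frequencies (58, 109, 26, 18, 14, 18) over 243 nodes."""
        table = cluster_frequency_table([1, 2, 3, 4, 5, 6], [58, 109, 26, 18, 14, 18])
        rows = {row["Cluster"]: row for _, row in table.iterrows()}
        assert rows[2]["Freq%"] == 44.86
        assert rows[2]["CumFreq"] == 167
        assert rows[2]["CumFreq%"] == 68.72
        assert rows[6]["Freq%"] == 7.41
        assert rows[6]["CumFreq"] == 243
        assert rows[6]["CumFreq%"] == 100.00

    def test_edgeless_graph(self):
        g = nx.DiGraph()
        g.add_nodes_from("abc")
        records, table = kcore_table(g)
        assert all(r.cluster_value == 0 for r in records)
        assert len(table) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_peeling_oracle(self, seed):
        g = random_digraph(35, 0.1, seed=seed)
        records, table = kcore_table(g)
        oracle = oracle_core_numbers(g)
        assert {r.node: r.cluster_value for r in records} == oracle
        assert table["CumFreq"].iloc[-1] == 35
        assert table["CumFreq%"].iloc[-1] == 100.00

    @pytest.mark.parametrize("seed", range(3))
    def test_kcore_subgraph_has_min_internal_degree_k(self, seed):
        g = random_digraph(35, 0.12, seed=seed)
        records, _ = kcore_table(g)
        core = {r.node: r.cluster_value for r in records}
        und = nx.Graph(g)
        und.remove_edges_from(nx.selfloop_edges(und))
        for k in sorted(set(core.values())):
            members = {n for n, c in core.items() if c >= k}
            for n in members:
                assert sum(1 for nb in und.neighbors(n) if nb in members) >= k


class TestRandomBaseline:
    def test_forced_complete_graph(self):
        b = random_baseline(10, 90, seed=0)
        assert b.clustering_coefficient == 1.0
        assert b.paths.diameter == 1

    def test_deterministic(self):
        a = random_baseline(243, 545, seed=4)
        b = random_baseline(243, 545, seed=4)
        assert a == b

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            random_baseline(5, 21, seed=0)

    def test_mean_projected_density(self):
        """Monte-Carlo over 50 seeds: undirected-projection density of
        G(243, 545) sits near 545 / C(243, 2) ≈ 0.0185."""
        target = 545 / (243 * 242 / 2)
        densities = []
        for seed in range(50):
            g = nx.gnm_random_graph(243, 545, seed=seed, directed=True)
            und = nx.Graph(g)
            densities.append(und.number_of_edges() / (243 * 242 / 2))
        assert np.mean(densities) == pytest.approx(target, rel=0.10)
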