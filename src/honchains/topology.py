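"""Topological statistics of the higher-order causation network.

Covers the standard diagnostic battery for accident-causation graphs:
degree metrics and the cumulative degree-distribution fit (scale-free
check), average shortest-path length and diameter with a size-matched
random baseline (small-world check), the mean clustering coefficient,
normalized betweenness centrality, and a k-core decomposition with the
conventional cluster-value frequency table.

Conventions
-----------
* Degrees count distinct directed edges; weights are ignored.
* Path metrics use unweighted directed shortest paths over reachable
  ordered pairs only (unreachable pairs are excluded and their number is
  recoverable from ``reachable_pairs``).
* Clustering and core numbers are computed on the undirected simple
  projection (reciprocal edges collapsed, self-loops removed).
* Betweenness is directed by default and normalized by (N−1)(N−2).
* The random baseline is a directed Erdős–Rényi G(N, M) graph with the
  same node and edge counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .hon import HONGraph, HONNode

logger = logging.getLogger("honchains")

__all__ = [
    "DegreeRecord",
    "DistributionFit",
    "PathMetrics",
    "CentralityRecord",
    "KCoreRecord",
    "BaselineMetrics",
    "TopologyReport",
    "degree_metrics",
    "cumulative_degree_distribution",
    "fit_degree_distribution",
    "path_metrics",
    "clustering_coefficient",
    "betweenness",
    "kcore_table",
    "random_baseline",
    "analyze_topology",
]


def _digraph(graph: HONGraph | nx.DiGraph) -> nx.DiGraph:
    return graph.graph if isinstance(graph, HONGraph) else graph


def _undirected_simple(g: nx.DiGraph) -> nx.Graph:
    und = nx.Graph(g)
    und.remove_edges_from(nx.selfloop_edges(und))
    return und


@dataclass(frozen=True)
class DegreeRecord:
    node: HONNode
    in_degree: int
    out_degree: int

    @property
    def all_degree(self) -> int:
        return self.in_degree + self.out_degree


def degree_metrics(
    graph: HONGraph | nx.DiGraph,
) -> tuple[list[DegreeRecord], float]:
    """Per-node in/out/all degrees and the network average degree 2E/N."""
    g = _digraph(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    records = [
        DegreeRecord(node=n, in_degree=g.in_degree(n), out_degree=g.out_degree(n))
        for n in sorted(g.nodes)
    ]
    average = 2.0 * g.number_of_edges() / g.number_of_nodes()
    return records, average


def cumulative_degree_distribution(
    records: Sequence[DegreeRecord],
) -> list[tuple[int, float]]:
    """P(K >= k) at every observed all-degree k; non-increasing, starts at 1."""
    if not records:
        raise ValueError("no degree records")
    degrees = np.array(sorted(r.all_degree for r in records))
    n = len(degrees)
    out = []
    for k in np.unique(degrees):
        out.append((int(k), float(np.sum(degrees >= k) / n)))
    return out


@dataclass(frozen=True)
class DistributionFit:
    coefficient: float
    exponent: float
    r_squared: float
    form: str = "power"  # "power": P = c·k^e; "exponential": P = c·e^(e·k)


def fit_degree_distribution(
    cumdist: Sequence[tuple[int, float]], form: str = "power"
) -> DistributionFit:
    """Least-squares fit of the cumulative degree distribution.

    ``form="power"`` regresses log P on log k (scale-free form c·k^e);
    ``form="exponential"`` regresses log P on k.  Points with k <= 0 or
    P <= 0 are unusable; at least 3 are required.
    """
    pts = [(k, p) for k, p in cumdist if k > 0 and p > 0]
    if len(pts) < 3:
        raise ValueError("need >= 3 points with k > 0 and P > 0 to fit")
    k = np.array([q[0] for q in pts], dtype=float)
    p = np.array([q[1] for q in pts], dtype=float)
    if form == "power":
        res = stats.linregress(np.log(k), np.log(p))
    elif form == "exponential":
        res = stats.linregress(k, np.log(p))
    else:
        raise ValueError(f"unknown fit form {form!r}")
    return DistributionFit(
        coefficient=float(np.exp(res.intercept)),
        exponent=float(res.slope),
        r_squared=float(res.rvalue**2),
        form=form,
    )


@dataclass(frozen=True)
class PathMetrics:
    average_path_length: float
    diameter: int
    reachable_pairs: int


def path_metrics(graph: HONGraph | nx.DiGraph) -> PathMetrics:
    """Unweighted directed shortest-path statistics over reachable ordered
    pairs (self-pairs and unreachable pairs excluded)."""
    g = _digraph(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        logger.warning("edgeless graph: path metrics are zero")
        return PathMetrics(0.0, 0, 0)
    total = 0
    pairs = 0
    diameter = 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if target == source:
                continue
            total += dist
            pairs += 1
            if dist > diameter:
                diameter = dist
    if pairs == 0:
        return PathMetrics(0.0, 0, 0)
    return PathMetrics(total / pairs, diameter, pairs)


def clustering_coefficient(graph: HONGraph | nx.DiGraph) -> float:
    """Mean local clustering on the undirected simple projection (nodes
    with fewer than two neighbours contribute 0)."""
    g = _digraph(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return float(nx.average_clustering(_undirected_simple(g)))


@dataclass(frozen=True)
class CentralityRecord:
    node: HONNode
    betweenness: float


def betweenness(
    graph: HONGraph | nx.DiGraph, directed: bool = True
) -> list[CentralityRecord]:
    """Normalized betweenness centrality (Brandes), endpoints excluded.

    Directed by default; ``directed=False`` computes on the undirected
    simple projection.  Normalization by (N−1)(N−2) puts values in [0, 1].
    """
    g = _digraph(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    target = g if directed else _undirected_simple(g)
    bc = nx.betweenness_centrality(target, normalized=True, weight=None)
    return [CentralityRecord(node=n, betweenness=float(bc[n])) for n in sorted(bc)]


@dataclass(frozen=True)
class KCoreRecord:
    node: HONNode
    cluster_value: int


def kcore_table(
    graph: HONGraph | nx.DiGraph,
) -> tuple[list[KCoreRecord], pd.DataFrame]:
    """Core numbers (iterative minimum-degree peeling on the undirected
    simple projection) and the cluster-value frequency table.

    The table lists Freq, Freq%, CumFreq, CumFreq% per cluster value in
    ascending order; the final cumulative row covers all N nodes
    (CumFreq% = 100.00).  Percentages are rounded to 2 decimals.
    """
    g = _digraph(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    core = nx.core_number(_undirected_simple(g))
    records = [KCoreRecord(node=n, cluster_value=core[n]) for n in sorted(core)]
    freq = pd.Series([r.cluster_value for r in records]).value_counts().sort_index()
    table = cluster_frequency_table(freq.index.tolist(), freq.values.tolist())
    return records, table


def cluster_frequency_table(
    clusters: Sequence[int], frequencies: Sequence[int]
) -> pd.DataFrame:
    """Build the cluster-value frequency table from (cluster, Freq) pairs.

    Cumulative percentages are computed from cumulative frequencies (not
    by summing rounded row percentages), so the final row is exactly
    100.00.
    """
    n = int(sum(frequencies))
    cum = np.cumsum(frequencies)
    return pd.DataFrame(
        {
            "Cluster": list(clusters),
            "Freq": list(frequencies),
            "Freq%": [round(100.0 * f / n, 2) for f in frequencies],
            "CumFreq": cum.astype(int).tolist(),
            "CumFreq%": [round(100.0 * c / n, 2) for c in cum],
        }
    )


@dataclass(frozen=True)
class BaselineMetrics:
    """Network-level metrics of one random G(N, M) replicate."""

    n_nodes: int
    n_edges: int
    seed: int
    average_degree: float
    paths: PathMetrics
    clustering_coefficient: float


def random_baseline(n_nodes: int, n_edges: int, seed: int) -> BaselineMetrics:
    """Directed Erdős–Rényi G(N, M) baseline: exactly ``n_edges`` distinct
    ordered pairs, no self-loops, uniform; seeded and reproducible."""
    if n_edges > n_nodes * (n_nodes - 1):
        raise ValueError(
            f"cannot place {n_edges} directed edges on {n_nodes} nodes"
        )
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed, directed=True)
    return BaselineMetrics(
        n_nodes=n_nodes,
        n_edges=n_edges,
        seed=seed,
        average_degree=2.0 * n_edges / n_nodes,
        paths=path_metrics(g),
        clustering_coefficient=clustering_coefficient(g),
    )


@dataclass
class TopologyReport:
    """Full statistics bundle for one higher-order causation network."""

    n_nodes: int
    n_first_order: int
    n_higher_order: int
    n_edges: int
    average_degree: float
    degree_records: list[DegreeRecord]
    cumulative_distribution: list[tuple[int, float]]
    fit: DistributionFit | None
    fit_exponential: DistributionFit | None
    paths: PathMetrics
    clustering_coefficient: float
    centralities: list[CentralityRecord]
    kcore_records: list[KCoreRecord]
    kcore_table: pd.DataFrame
    baseline: list[BaselineMetrics] = field(default_factory=list)


def analyze_topology(
    hon: HONGraph,
    baseline_seed: int | None = None,
    baseline_replicates: int = 0,
    directed_betweenness: bool = True,
) -> TopologyReport:
    """Compute the full topology report, optionally with seeded random
    G(N, M) baseline replicates (seeds ``baseline_seed .. +replicates-1``)."""
    records, avg = degree_metrics(hon)
    cumdist = cumulative_degree_distribution(records)
    try:
        fit = fit_degree_distribution(cumdist, form="power")
        fit_exp = fit_degree_distribution(cumdist, form="exponential")
    except ValueError:
        fit = fit_exp = None
    krecords, ktable = kcore_table(hon)
    baseline = []
    if baseline_replicates and baseline_seed is not None:
        baseline = [
            random_baseline(
                hon.graph.number_of_nodes(), hon.graph.number_of_edges(),
                seed=baseline_seed + i,
            )
            for i in range(baseline_replicates)
        ]
    return TopologyReport(
        n_nodes=hon.graph.number_of_nodes(),
        n_first_order=len(hon.first_order_nodes),
        n_higher_order=len(hon.higher_order_nodes),
        n_edges=hon.graph.number_of_edges(),
        average_degree=avg,
        degree_records=records,
        cumulative_distribution=cumdist,
        fit=fit,
        fit_exponential=fit_exp,
        paths=path_metrics(hon),
        clustering_coefficient=clustering_coefficient(hon),
        centralities=betweenness(hon, directed=directed_betweenness),
        kcore_records=krecords,
        kcore_table=ktable,
        baseline=baseline,
    )
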