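"""Higher-order network construction from accident causal chains.

The conventional causation network joins factors that are adjacent in some
chain — a first-order Markov assumption that discards path history.  Here
each factor's successor distribution is tested for dependence on deeper
predecessor context and, where the dependence is significant, the factor
is split into context-conditioned *higher-order nodes* so the network
itself carries the memory.

The procedure, in the order this module implements it:

1.  Count subpaths.  For every adjacent pair (i, j) in every chain and
    every context depth, the traversal count W(context, i → j) is
    accumulated (:func:`count_subpaths`).

2.  Transfer probabilities.  The first-order probability is

        P(i → j) = W(i → j) / Σ_h W(i → h)

    and the context-conditioned probability replaces the counts with
    their context-restricted versions (:func:`transfer_probability`).

3.  Dependency testing.  A candidate context extension is accepted when
    the Kullback–Leibler divergence (in bits) between the extended and
    the currently accepted successor distribution exceeds a dynamic
    threshold δ = α·order / log2(1 + support), which tightens for deeper
    orders and relaxes with more supporting observations
    (:func:`kl_divergence`, :func:`dynamic_threshold`).  Accepted
    contexts are grown one predecessor at a time until nothing deeper is
    significant (:func:`extract_rules`).

4.  Wiring.  First-order rules become plain nodes ("H12|") and weighted
    edges; each accepted context becomes a higher-order node ("A1|H12")
    carrying its outgoing rules; finally every edge into a plain node is
    rewired to the deepest context-matching variant of its target
    (:func:`build_network`).

Contexts are stored most-recent predecessor first, matching the display
notation "A3|V11.V10" (A3 reached from V11, V11 reached from V10).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .chains import AccidentChain

__all__ = [
    "SubpathFrequencyTable",
    "TransitionDistribution",
    "DependencyTest",
    "DependencyRule",
    "HONNode",
    "HONGraph",
    "count_subpaths",
    "transfer_probability",
    "kl_divergence",
    "dynamic_threshold",
    "extract_rules",
    "compact_rules",
    "build_network",
    "project_first_order",
    "DEFAULT_ALPHA",
    "DEFAULT_MAX_ORDER",
    "DEFAULT_MIN_SUPPORT",
]

DEFAULT_ALPHA = 0.4
DEFAULT_MAX_ORDER = 5
DEFAULT_MIN_SUPPORT = 1

Context = tuple[str, ...]


def _as_codes(chain: AccidentChain | Sequence[str]) -> tuple[str, ...]:
    if isinstance(chain, AccidentChain):
        return chain.codes
    return tuple(chain)


# --------------------------------------------------------------------------
# Subpath counting
# --------------------------------------------------------------------------

@dataclass
class SubpathFrequencyTable:
    """Traversal counts W(context, source → target) for all context depths
    up to ``order - 1`` (``order`` = maximum subpath order represented).

    Contexts are most-recent-first tuples; the empty context holds the
    first-order counts.
    """

    counts: dict[tuple[Context, str], Counter] = field(default_factory=dict)
    order: int = 1

    def successors(self, context: Context, source: str) -> Counter:
        try:
            return self.counts[(tuple(context), source)]
        except KeyError:
            raise KeyError(
                f"no observed successor for prefix context={context!r} source={source!r}"
            ) from None

    def support(self, context: Context, source: str) -> int:
        return sum(self.successors(context, source).values())

    def prefixes(self) -> list[tuple[Context, str]]:
        return sorted(self.counts)

    def __contains__(self, prefix: tuple[Context, str]) -> bool:
        return (tuple(prefix[0]), prefix[1]) in self.counts


def count_subpaths(
    chains: Iterable[AccidentChain | Sequence[str]], order: int = 1
) -> SubpathFrequencyTable:
    """Count every subpath of order 1..``order`` over the corpus.

    An order-k subpath is a window of k+1 consecutive factors; its last
    element is the target, the one before it the source, and the earlier
    elements form the context (stored most-recent-first).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    counts: dict[tuple[Context, str], Counter] = defaultdict(Counter)
    for chain in chains:
        codes = _as_codes(chain)
        for k in range(1, order + 1):
            for end in range(k, len(codes)):
                window = codes[end - k : end + 1]
                context = tuple(reversed(window[:-2]))
                counts[(context, window[-2])][window[-1]] += 1
    return SubpathFrequencyTable(counts=dict(counts), order=order)


# --------------------------------------------------------------------------
# Transfer probabilities and the dependency test
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionDistribution:
    """Successor distribution of a (context, source) prefix."""

    context: Context
    source: str
    probs: Mapping[str, float]
    support: int


def transfer_probability(
    table: SubpathFrequencyTable, context: Sequence[str], source: str
) -> TransitionDistribution:
    """Normalized successor distribution of a prefix (empty context =
    first-order transfer probability)."""
    ctx = tuple(context)
    succ = table.successors(ctx, source)
    total = sum(succ.values())
    return TransitionDistribution(
        context=ctx,
        source=source,
        probs={j: w / total for j, w in sorted(succ.items())},
        support=total,
    )


def kl_divergence(
    extended: TransitionDistribution, base: TransitionDistribution
) -> float:
    """Kullback–Leibler divergence D(extended ‖ base) in bits.

    Every successor observed under the extended context must also be
    observed under the base context (extended counts are a subset of base
    counts); a missing one signals a counting bug upstream.
    """
    if extended.source != base.source:
        raise ValueError("distributions condition on different sources")
    div = 0.0
    for j, p in extended.probs.items():
        q = base.probs.get(j, 0.0)
        if q <= 0.0:
            raise ValueError(
                f"successor {j!r} present in extended context {extended.context!r} "
                f"but absent from base context {base.context!r}"
            )
        if p > 0.0:
            div += p * math.log2(p / q)
    return max(div, 0.0)


def dynamic_threshold(order: int, support: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Dynamic significance threshold δ = α·order / log2(1 + support).

    Deeper candidate orders must clear a higher bar; more supporting
    observations lower it.
    """
    if order < 2:
        raise ValueError("threshold applies to candidate orders >= 2")
    if support < 1:
        raise ValueError("support must be >= 1")
    return alpha * order / math.log2(1 + support)


@dataclass(frozen=True)
class DependencyTest:
    """Outcome of one context-extension significance test."""

    context: Context
    source: str
    divergence: float
    threshold: float
    order: int
    support: int

    @property
    def significant(self) -> bool:
        return self.divergence > self.threshold


@dataclass(frozen=True, order=True)
class DependencyRule:
    """A validated path dependency: with ``context`` behind it, ``source``
    moves to ``target`` with the given traversal frequency and transfer
    probability.  Empty context = first-order rule."""

    source: str
    context: Context
    target: str
    frequency: int
    probability: float

    @property
    def order(self) -> int:
        return len(self.context) + 1


# --------------------------------------------------------------------------
# Rule extraction
# --------------------------------------------------------------------------

def extract_rules(
    chains: Iterable[AccidentChain | Sequence[str]],
    max_order: int = DEFAULT_MAX_ORDER,
    min_support: int = DEFAULT_MIN_SUPPORT,
    alpha: float = DEFAULT_ALPHA,
    table: SubpathFrequencyTable | None = None,
    tests: list[DependencyTest] | None = None,
) -> list[DependencyRule]:
    """Extract first- and higher-order path dependencies from a corpus.

    All first-order pairs with frequency >= ``min_support`` are emitted.
    For each source, candidate contexts grow one predecessor at a time;
    a candidate of order k is accepted when its support reaches
    ``min_support`` and its KL divergence from the deepest already
    accepted distribution exceeds the dynamic threshold.  Growth
    continues only from accepted contexts and stops at ``max_order``,
    when no candidate is significant, or when the extended distribution
    is degenerate with nothing deeper observed.

    Pass ``table`` to reuse a pre-computed count table (it must have been
    built at ``order >= max_order``); pass ``tests`` to collect the
    individual significance tests for reporting.

    Returns rules sorted by (source, context, target) — deterministic for
    a given corpus.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if table is None:
        table = count_subpaths(chains, order=max_order)
    elif table.order < max_order:
        raise ValueError("count table shallower than max_order")

    # group observed contexts by (source, depth) for candidate generation
    by_source_depth: dict[tuple[str, int], list[Context]] = defaultdict(list)
    for ctx, source in table.prefixes():
        by_source_depth[(source, len(ctx))].append(ctx)

    rules: list[DependencyRule] = []
    sources = sorted({source for ctx, source in table.prefixes() if not ctx})
    for source in sources:
        base = transfer_probability(table, (), source)
        for target, w in sorted(base.probs.items()):
            freq = table.successors((), source)[target]
            if freq >= min_support:
                rules.append(
                    DependencyRule(
                        source=source,
                        context=(),
                        target=target,
                        frequency=freq,
                        probability=base.probs[target],
                    )
                )
        # grow accepted contexts breadth-first
        frontier: list[tuple[Context, TransitionDistribution]] = [((), base)]
        while frontier:
            next_frontier: list[tuple[Context, TransitionDistribution]] = []
            for ctx, accepted_dist in frontier:
                k = len(ctx) + 2  # candidate order
                if k > max_order:
                    continue
                for cand in by_source_depth.get((source, len(ctx) + 1), ()):
                    if cand[: len(ctx)] != ctx:
                        continue
                    extended = transfer_probability(table, cand, source)
                    if extended.support < min_support:
                        continue
                    thr = dynamic_threshold(k, extended.support, alpha)
                    div = kl_divergence(extended, accepted_dist)
                    if tests is not None:
                        tests.append(
                            DependencyTest(
                                context=cand,
                                source=source,
                                divergence=div,
                                threshold=thr,
                                order=k,
                                support=extended.support,
                            )
                        )
                    if div > thr:
                        for target, p in sorted(extended.probs.items()):
                            freq = table.successors(cand, source)[target]
                            rules.append(
                                DependencyRule(
                                    source=source,
                                    context=cand,
                                    target=target,
                                    frequency=freq,
                                    probability=p,
                                )
                            )
                        next_frontier.append((cand, extended))
            frontier = next_frontier
    return sorted(rules)


def compact_rules(rules: Iterable[DependencyRule]) -> list[DependencyRule]:
    """Drop every rule that is fully refined by a deeper accepted rule.

    A rule is superseded when some deeper rule shares its source and
    target and extends its context; what remains is the compact rule list
    as conventionally reported (shallow rules only where no refinement
    exists).
    """
    rules = list(rules)
    kept = []
    for r in rules:
        refined = any(
            r2.source == r.source
            and r2.target == r.target
            and len(r2.context) > len(r.context)
            and r2.context[: len(r.context)] == r.context
            for r2 in rules
        )
        if not refined:
            kept.append(r)
    return sorted(kept)


# --------------------------------------------------------------------------
# Network wiring
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class HONNode:
    """A network node: a base factor with (possibly empty) predecessor
    context.  Displayed "A6|" (first order) or "A1|H05", "A3|V11.V10"
    (most-recent predecessor first)."""

    base: str
    context: Context = ()

    @property
    def order(self) -> int:
        return len(self.context) + 1

    @property
    def label(self) -> str:
        return f"{self.base}|{'.'.join(self.context)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_node_label(label: str) -> HONNode:
    """Inverse of :attr:`HONNode.label` ("A1|H05" → base A1, context (H05,))."""
    base, _, ctx = label.partition("|")
    context = tuple(c for c in ctx.split(".") if c)
    return HONNode(base=base, context=context)


@dataclass
class HONGraph:
    """The higher-order causation network: a directed graph over
    :class:`HONNode`, edge weights = traversal frequencies, plus the rule
    set it was built from."""

    graph: nx.DiGraph
    rules: list[DependencyRule] = field(default_factory=list)

    @property
    def nodes(self) -> list[HONNode]:
        return sorted(self.graph.nodes)

    @property
    def first_order_nodes(self) -> list[HONNode]:
        return [n for n in self.nodes if getattr(n, "order", 1) == 1]

    @property
    def higher_order_nodes(self) -> list[HONNode]:
        return [n for n in self.nodes if getattr(n, "order", 1) > 1]

    def edges(self) -> list[tuple[HONNode, HONNode, int]]:
        return sorted(
            (u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)
        )

    def total_weight(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _rule_weights(
    rules: Sequence[DependencyRule], table: SubpathFrequencyTable
) -> dict[DependencyRule, int]:
    """Attribute every traversal to the deepest accepted context covering it.

    W(rule) starts from the table count of its prefix+target and loses
    the counts claimed by accepted one-step-deeper contexts, so a shallow
    rule keeps only the traversals no refinement explains.  Rules whose
    traversals are all claimed end up with weight 0 and produce no edge.
    """
    accepted: dict[str, set[Context]] = defaultdict(set)
    for r in rules:
        accepted[r.source].add(r.context)
    weights: dict[DependencyRule, int] = {}
    for r in rules:
        if (r.context, r.source) not in table:
            raise ValueError(
                f"rule prefix {r.context!r}|{r.source!r} absent from the count table"
            )
        w = table.successors(r.context, r.source)[r.target]
        for deeper in accepted[r.source]:
            if len(deeper) == len(r.context) + 1 and deeper[: len(r.context)] == r.context:
                if (deeper, r.source) in table:
                    w -= table.successors(deeper, r.source).get(r.target, 0)
        weights[r] = w
    return weights


def build_network(
    rules: Sequence[DependencyRule], table: SubpathFrequencyTable
) -> HONGraph:
    """Wire validated dependency rules into the higher-order network.

    (a) first-order rules become plain nodes and weighted edges;
    (b) each accepted higher-order context becomes one node carrying its
    outgoing rules; (c) every edge whose target has a context-matching
    higher-order variant is rewired to the deepest matching variant, and
    plain nodes stripped of all incident edges are dropped.
    """
    rules = sorted(rules)
    weights = _rule_weights(rules, table)

    raw_edges: list[tuple[HONNode, HONNode, int]] = []
    hon_nodes: set[HONNode] = set()
    for r in rules:
        w = weights[r]
        if w <= 0:
            continue
        src = HONNode(r.source, r.context)
        dst = HONNode(r.target, ())
        raw_edges.append((src, dst, w))
        if src.order > 1:
            hon_nodes.add(src)

    # variants of each base factor, deepest context first
    variants: dict[str, list[HONNode]] = defaultdict(list)
    for node in sorted(hon_nodes, key=lambda n: (-len(n.context), n.context)):
        variants[node.base].append(node)

    def rewire(origin: HONNode, target: HONNode) -> HONNode:
        history = (origin.base,) + origin.context
        for cand in variants.get(target.base, ()):
            g = cand.context
            if len(g) <= len(history) and history[: len(g)] == g:
                return cand
        return target

    g = nx.DiGraph()
    for src, dst, w in raw_edges:
        dst = rewire(src, dst)
        if g.has_edge(src, dst):
            g[src][dst]["weight"] += w
        else:
            g.add_edge(src, dst, weight=w)
    # higher-order nodes exist by construction; drop plain nodes isolated
    # by the rewiring
    for node in [n for n in g.nodes if g.degree(n) == 0]:
        g.remove_node(node)
    return HONGraph(graph=g, rules=list(rules))


def project_first_order(hon: HONGraph) -> HONGraph:
    """Collapse every node to its base factor, summing edge weights.

    Produces the memoryless (traditional Markov) causation network the
    higher-order model refines; total edge weight is conserved.
    """
    g = nx.DiGraph()
    for u, v, w in hon.edges():
        a, b = HONNode(u.base, ()), HONNode(v.base, ())
        if g.has_edge(a, b):
            g[a][b]["weight"] += w
        else:
            g.add_edge(a, b, weight=w)
    return HONGraph(graph=g, rules=list(hon.rules))
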