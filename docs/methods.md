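# Methods

## The model

An accident corpus is a set of chains, each an ordered sequence of coded
causal factors from a fixed taxonomy of 67 atomic causes in six families
(Human H01–H12, Vehicle V01–V16, Hazardous Materials HM01–HM09,
Management M01–M08, Environment E01–E13, Accident type A1–A9), plus
composite codes for simultaneous factors (`E3H3` = turning road together
with fast driving).  Composites are opaque nodes: they are never linked
to or merged with their atomic parts.  Canonical codes are single-digit
for the A family and two-digit zero-padded elsewhere; both padded and
compact spellings are accepted on input, and composite tokenization is
greedy left-to-right longest-match, so a given string always splits the
same way.

The network model is a variable-order Markov representation of the
corpus.  For every prefix (context *g*, source *i*) the successor
distribution is the normalized traversal count table; the empty context
gives the first-order transfer probability.  A context extension of order
k is accepted as a path dependency when

    D_KL(extended ‖ accepted) > δ(k, support) = α · k / log₂(1 + support)

where "accepted" is the distribution of the deepest already-accepted
prefix it extends, D_KL is in bits, and the comparison is strict.
Accepted contexts grow breadth-first one predecessor at a time; growth
stops at `max_order`, when no candidate clears the threshold, or
naturally when the extended distribution is degenerate and nothing deeper
is observed (a degenerate extension of a degenerate distribution has
zero divergence).

### The threshold and its default

The δ family above is the standard support- and order-dependent cutoff
for variable-order dependency detection; α scales its strictness.  The
default α = 0.4 is calibrated on the canonical two-chain example: a jump
from a 0.5/0.5 successor split to a certain successor at order 2 with a
single supporting observation carries exactly 1 bit of divergence, and a
threshold of α·2/log₂(2) = 0.8 admits it, while the unscaled form
(α = 1, δ = 2) would reject what is plainly a real dependency at that
scale.  α, `max_order` (default 5) and `min_support` (default 1 —
single-observation dependencies are meaningful in small curated corpora;
raise it for large noisy ones) are exposed on the CLI and every API
entry point.

### Wiring

Rule wiring follows three steps: (a) first-order rules become plain
nodes `i|` and weighted edges; (b) each accepted context becomes one
higher-order node `i|g` (display: most recent predecessor first,
`A3|V11.V10`) whose outgoing edges carry its rules; (c) every edge into
a plain node is redirected to the deepest variant of its target whose
context matches the edge's origin history (the origin node's base
followed by its own context).  Plain nodes stripped of all incident
edges by the rewiring are dropped.

Edge weights are raw traversal frequencies, attributed exclusively: each
adjacent-pair traversal in the corpus is claimed by the deepest accepted
context that covers it, computed by subtracting child-context counts
from each rule's prefix count.  Consequences: a first-order rule fully
explained by its refinements carries weight 0 and produces no edge
(which is why the two-chain example ends with 6 + 2 nodes and no plain
`A1|`), total edge weight equals the corpus transition count when
`min_support` is 1, and the first-order projection (collapse every node
to its base, sum weights) conserves total weight exactly.  Probabilities
are recoverable by per-node normalization.

## Topology conventions

* Degrees count distinct directed edges, weights ignored; average degree
  is 2E/N.
* The cumulative degree distribution P(K ≥ k) is fitted by least squares
  in log–log space (power form c·k^e, the scale-free diagnostic); a
  semilog (exponential) fit is computed alongside so the better model is
  reportable.  At least 3 distinct positive degrees are required.
* Path metrics use unweighted directed shortest paths over reachable
  ordered pairs only; a directed causation graph is rarely strongly
  connected, and exclusion is the only convention that yields finite
  values.  The reachable-pair count is reported for transparency.
* Clustering and core numbers are computed on the undirected simple
  projection (reciprocal edges collapsed, self-loops removed); clustering
  is the Watts–Strogatz mean local coefficient with degree-<2 nodes
  contributing 0; core numbers come from iterative minimum-degree
  peeling, reported as an ascending cluster-value frequency table whose
  cumulative percentages are computed from cumulative counts (so the
  last row is exactly 100.00).
* Betweenness is Brandes on the directed graph (a flag switches to the
  undirected projection), normalized by (N−1)(N−2) so values lie in
  [0, 1]; endpoints are excluded.
* The random baseline is a directed Erdős–Rényi G(N, M) graph — exactly
  M distinct ordered pairs, no self-loops — with the observed N and M,
  seeded; the pipeline averages a configurable number of replicates.
  How the original small-world baselines for such networks were generated
  is generally unstated in the literature, so the baseline here is
  defined, seeded and reported rather than matched to any printed value.

## The synthetic generator

`ChainModel` is a first-order backbone (start distribution, row-
stochastic transition rows, chain-length distribution, optional absorbing
states) plus planted overrides: contexts of ≥ 2 states whose successor
distribution replaces the base row when the walk's recent history
matches, longest context winning — deliberately symmetric with how
deeper rules shadow shallower ones in the builder.  The default length
distribution is uniform on {3, 4, 5, 6}, matching the chain lengths
typical of curated accident reports; all sampling flows from one
explicit seed.

What the generator emulates: variable-length coded chains with genuine
higher-order structure of known location and strength.  What it does
not: the empirical frequency profile of any real accident corpus, coding
noise or mislabeled factors, and chain-extraction ambiguity from prose
reports.  Passing tests therefore demonstrate that the detector recovers
dependencies that exist and rejects ones that do not under clean
sampling; they do not certify behaviour under coding error.

Test problem sizes: planted-recovery and null-control checks use 5000
chains across ≥ 3 seeds (sampling error on a transition probability at
that size is ≈ 0.01–0.02, comfortably inside the ±0.05 assertion band);
oracle-equivalence checks use 20 seeded random graphs of 30–50 nodes,
where brute-force enumeration (Floyd–Warshall, triangle counting,
explicit geodesic enumeration, repeated peeling) is exact and fast.

## Degenerate inputs and tie-breaks

Chains shorter than 2 factors are rejected at parse time.  Empty corpora
yield empty tables; edgeless graphs yield zero path metrics with a
warning; prefixes never observed raise rather than returning empty
distributions (an unobserved prefix in rule wiring indicates an internal
inconsistency and is reported as such).  All iteration is over sorted
keys and all rankings break ties by node label, so a given corpus and
configuration produce byte-identical output bundles.

## Known limitations

* The exclusive-attribution weighting means shallow-rule edge weights
  depend on which refinements were accepted; with small α the graph can
  fragment into many low-weight context nodes.
* First-order rules are kept alongside their refinements in the rule
  table (for traversals the refinements do not cover); consumers wanting
  the compact rule list should use `compact_rules`.
* Statistical control of the KL test is by the δ heuristic, not by a
  calibrated false-positive rate; the null-control tests characterize it
  empirically at the default α only.
* Betweenness and path metrics ignore edge weights by design (the graph
  is a causation structure, not a flow network).
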