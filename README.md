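# honchains

Higher-order causation networks from coded accident causal chains.

Accident investigators in hazardous-materials road transport (and similar
domains) summarize each accident as an ordered *causal chain* of coded
factors — e.g. `H10→H05→A1→A6`: unfamiliar road → improper overtaking →
collision → leakage.  The conventional causation network links factors
that are adjacent in some chain, which assumes the next cause depends only
on the current one (a first-order Markov assumption).  In practice the
route *into* a factor matters: a collision reached via improper overtaking
may have very different consequences than one reached via fatigue driving.

`honchains` builds a **higher-order network (HON)** that keeps that
memory.  It is aimed at safety analysts and network researchers who have a
corpus of coded event chains and want the context-conditioned causation
graph plus its standard topological diagnostics.

## Model

For a factor *i* with observed traversal counts *W*, the first-order
transfer probability is

    P(i→j) = W(i→j) / Σ_h W(i→h)

and the probability conditioned on predecessor context *g* is

    P(i|g→j) = W(i|g→j) / Σ_h W(i|g→h)

A context extension is accepted as a *path dependency* when the
Kullback–Leibler divergence (bits)

    D_KL( P(i|g→·) ‖ P(i→·) ) > δ,   δ = α · order / log₂(1 + support)

i.e. when conditioning on the deeper context moves the successor
distribution by more than a threshold that tightens with order and relaxes
with supporting observations (default α = 0.4).  Accepted contexts grow
one predecessor at a time until nothing deeper is significant.

Validated rules are wired into a directed weighted graph: first-order
rules become plain nodes (`H12|`) and edges; each accepted context becomes
a higher-order node (`A1|H12`, `A3|V11.V10` — most recent predecessor
first) carrying its outgoing rules; finally every edge into a plain node
is rewired to the deepest context-matching variant of its target, so walks
on the graph respect the detected memory.  Edge weights are raw traversal
frequencies; each corpus traversal is attributed to the deepest rule that
covers it, so total weight is conserved under first-order projection.

The topology battery covers degree metrics and the cumulative
degree-distribution fit (scale-free check), shortest-path length and
diameter against a seeded directed G(N, M) baseline (small-world check),
mean clustering, normalized betweenness centrality and a k-core
decomposition with the cluster-value frequency table.

Because real accident corpora are rarely public, the package ships a
seeded synthetic-chain generator: a first-order backbone plus *planted*
higher-order overrides, so detection can be validated against known ground
truth (planted rules must be recovered; override-free corpora must yield
zero higher-order nodes).

## Worked example

With `chains.txt` containing the two chains

```
H10→H05→A01→A06
H01→A01→V04→A07
```

run

```sh
honchains run --input chains.txt --out demo --baseline-reps 5 --seed 1
```

which prints

```
Higher-order causation network summary
======================================
Nodes: 8 (6 first-order, 2 higher-order)
Edges: 6
Average degree: 1.50
Average path length: 1.67 (over 12 reachable ordered pairs)
Diameter: 3
Clustering coefficient: 0.0000
...
```

Both chains pass through collision (`A1`), whose unconditioned successor
split is P(A1→A6) = P(A1→V04) = 0.5.  Conditioning on the predecessor
makes both transitions certain — P(A1|H05→A6) = P(A1|H01→V04) = 1.0, a
divergence of 1 bit against a threshold of 0.8 — so `A1` is split into the
two second-order nodes `A1|H05` and `A1|H01` and disappears as a plain
node: 6 first-order + 2 higher-order nodes.  The rule table written to
`demo/rules.csv`:

```
context,source,target,frequency,probability,order
,A1,A6,1,0.5000,1
,A1,V04,1,0.5000,1
H01,A1,V04,1,1.0000,2
H05,A1,A6,1,1.0000,2
,H01,A1,1,1.0000,1
,H05,A1,1,1.0000,1
,H10,H05,1,1.0000,1
,V04,A7,1,1.0000,1
```

The bundle also contains the Pajek graph (`graph.net`), edge list,
topology report (`topology.json`), per-node degree/betweenness/core
tables, and a manifest sufficient to re-run the pipeline.  Other
subcommands: `build` (chains → rules + graph), `analyze` (Pajek graph →
topology), `simulate` (generator spec → chain file).

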