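"""Synthetic accident-chain corpora with planted higher-order dependencies.

The study corpus of real accident chains is not public, so the pipeline is
exercised on simulated corpora.  A :class:`ChainModel` is a first-order
Markov backbone (start distribution, row-stochastic transition matrix,
chain-length distribution) plus *overrides*: specific predecessor contexts
whose successor distribution replaces the base row whenever the context
matches.  Overrides are the planted ground truth that higher-order
dependency extraction is expected to recover; a model without overrides is
a pure first-order null under which no higher-order rule should survive.

Matching is longest-context-wins, mirroring how deeper dependency rules
shadow shallower ones in the network builder.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .chains import AccidentChain, CausalFactor, parse_factor

__all__ = [
    "ChainModel",
    "GeneratorConfig",
    "generate_chains",
    "model_from_chains",
    "load_model",
    "save_model",
]

_TOL = 1e-9


def _check_dist(name: str, dist: Mapping[str, float]) -> None:
    if not dist:
        raise ValueError(f"{name}: empty distribution")
    total = float(sum(dist.values()))
    if abs(total - 1.0) > _TOL:
        raise ValueError(f"{name}: probabilities sum to {total}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name}: negative probability")


@dataclass
class ChainModel:
    """First-order backbone with planted higher-order overrides.

    Parameters
    ----------
    states
        Canonical factor codes the model walks over.
    start_dist
        Probability of each state opening a chain.
    base_transitions
        ``base_transitions[i][j]`` = P(next=j | current=i).  Rows may be
        missing for states that only ever terminate chains.
    overrides
        Mapping *context* → successor distribution.  A context is a tuple
        of >= 2 states ending in the current state, oldest first:
        ``("H01", "A1")`` overrides the successor row of ``A1`` whenever
        the walk reached A1 from H01.  The longest matching context wins.
    length_dist
        Distribution over chain lengths (minimum 2).
    terminal_states
        States that absorb the walk early if hit.
    """

    states: list[str]
    start_dist: dict[str, float]
    base_transitions: dict[str, dict[str, float]]
    overrides: dict[tuple[str, ...], dict[str, float]] = field(default_factory=dict)
    length_dist: dict[int, float] = field(
        default_factory=lambda: {3: 0.25, 4: 0.25, 5: 0.25, 6: 0.25}
    )
    terminal_states: frozenset[str] = frozenset()

    def validate(self) -> None:
        if not self.states:
            raise ValueError("model has no states")
        _check_dist("start_dist", self.start_dist)
        for i, row in self.base_transitions.items():
            _check_dist(f"base_transitions[{i}]", row)
        _check_dist("length_dist", {str(k): v for k, v in self.length_dist.items()})
        if any(int(length) < 2 for length in self.length_dist):
            raise ValueError("length_dist contains lengths < 2")
        for ctx, row in self.overrides.items():
            if len(ctx) < 2:
                raise ValueError(f"override context {ctx} shorter than 2 states")
            if ctx[-1] not in self.base_transitions:
                raise ValueError(
                    f"override context {ctx} does not end in a state with a base row"
                )
            _check_dist(f"overrides[{ctx}]", row)


@dataclass
class GeneratorConfig:
    n_chains: int
    seed: int
    model: ChainModel

    def validate(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        self.model.validate()


def _draw(rng: np.random.Generator, dist: Mapping, keys: Sequence) -> object:
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs /= probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def generate_chains(config: GeneratorConfig) -> list[AccidentChain]:
    """Sample ``n_chains`` accident chains from the model, reproducibly.

    Each chain draws a target length, a start state, then walks: at each
    step the successor distribution is the deepest override whose context
    matches the walk's recent history, falling back to the base row of the
    current state.  The walk stops early at a terminal state or when the
    current state has no successor row.
    """
    config.validate()
    model = config.model
    rng = np.random.default_rng(config.seed)

    # index overrides by current state, deepest first
    by_state: dict[str, list[tuple[tuple[str, ...], dict[str, float]]]] = defaultdict(list)
    for ctx in sorted(model.overrides, key=lambda c: (-len(c), c)):
        by_state[ctx[-1]].append((ctx, model.overrides[ctx]))

    start_keys = sorted(model.start_dist)
    length_keys = sorted(model.length_dist)
    factor_cache: dict[str, CausalFactor] = {}

    def factor(code: str) -> CausalFactor:
        if code not in factor_cache:
            factor_cache[code] = parse_factor(code)
        return factor_cache[code]

    chains: list[AccidentChain] = []
    for k in range(config.n_chains):
        length = int(_draw(rng, model.length_dist, length_keys))
        walk = [str(_draw(rng, model.start_dist, start_keys))]
        while len(walk) < length:
            current = walk[-1]
            if current in model.terminal_states and len(walk) >= 2:
                break
            row = None
            for ctx, override_row in by_state.get(current, ()):
                if len(ctx) <= len(walk) and tuple(walk[-len(ctx):]) == ctx:
                    row = override_row
                    break
            if row is None:
                row = model.base_transitions.get(current)
            if row is None:
                break
            walk.append(str(_draw(rng, row, sorted(row))))
        if len(walk) < 2:
            raise ValueError(
                f"chain {k} ended with a single state ({walk[0]}): the start state "
                "has no successor row"
            )
        chains.append(
            AccidentChain(factors=tuple(factor(c) for c in walk), source_id=f"sim:{k}")
        )
    return chains


def model_from_chains(
    chains: Sequence[AccidentChain | Sequence[str]], order: int = 1
) -> ChainModel:
    """Fit a maximum-likelihood :class:`ChainModel` to a corpus.

    Start, length and first-order transition estimates are empirical
    frequencies; for ``order`` >= 2 an override is populated for every
    observed context of length 2..order.  Useful for simulation
    round-trips (generate → refit → compare).
    """
    if not chains:
        raise ValueError("empty corpus")
    if order < 1:
        raise ValueError("order must be >= 1")
    seqs = [c.codes if isinstance(c, AccidentChain) else tuple(c) for c in chains]

    starts = Counter(s[0] for s in seqs)
    lengths = Counter(len(s) for s in seqs)
    pair_counts: dict[str, Counter] = defaultdict(Counter)
    ctx_counts: dict[tuple[str, ...], Counter] = defaultdict(Counter)
    for seq in seqs:
        for t in range(len(seq) - 1):
            pair_counts[seq[t]][seq[t + 1]] += 1
            for depth in range(2, order + 1):
                if t - depth + 1 >= 0:
                    ctx = tuple(seq[t - depth + 1 : t + 1])
                    ctx_counts[ctx][seq[t + 1]] += 1

    def normalize(counter: Counter) -> dict:
        total = sum(counter.values())
        return {k: v / total for k, v in sorted(counter.items())}

    states = sorted({s for seq in seqs for s in seq})
    return ChainModel(
        states=states,
        start_dist=normalize(starts),
        base_transitions={s: normalize(c) for s, c in sorted(pair_counts.items())},
        overrides={ctx: normalize(c) for ctx, c in sorted(ctx_counts.items())},
        length_dist=normalize(lengths),
    )


# --------------------------------------------------------------------------
# Model spec files (YAML)
# --------------------------------------------------------------------------

def save_model(model: ChainModel, path: str | Path, seed: int | None = None) -> None:
    doc: dict = {
        "states": list(model.states),
        "start": dict(model.start_dist),
        "transitions": {i: dict(row) for i, row in model.base_transitions.items()},
        "overrides": [
            {"context": list(ctx), "successors": dict(row)}
            for ctx, row in sorted(model.overrides.items())
        ],
        "lengths": {int(k): float(v) for k, v in model.length_dist.items()},
    }
    if model.terminal_states:
        doc["terminal"] = sorted(model.terminal_states)
    if seed is not None:
        doc["seed"] = int(seed)
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def load_model(path: str | Path) -> tuple[ChainModel, int | None]:
    """Read a model spec file; returns the model and the optional seed."""
    with Path(path).open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    model = ChainModel(
        states=[str(s) for s in doc["states"]],
        start_dist={str(k): float(v) for k, v in doc["start"].items()},
        base_transitions={
            str(i): {str(j): float(p) for j, p in row.items()}
            for i, row in doc["transitions"].items()
        },
        overrides={
            tuple(str(s) for s in item["context"]): {
                str(j): float(p) for j, p in item["successors"].items()
            }
            for item in doc.get("overrides", [])
        },
        length_dist={int(k): float(v) for k, v in doc.get("lengths", {3: 0.25, 4: 0.25, 5: 0.25, 6: 0.25}).items()},
        terminal_states=frozenset(str(s) for s in doc.get("terminal", [])),
    )
    model.validate()
    seed = doc.get("seed")
    return model, (int(seed) if seed is not None else None)
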