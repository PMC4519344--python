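"""Discrete-time Markov chain of cognate birth, spread and death.

Each node i holds a non-empty set V_i^t of cognates for one concept.  At every
step each node draws its next set from the non-empty power set of a candidate
pool

    C_i^t = {new word} ∪ V_i^{t-1} ∪ ⋃_{j ∈ N_i} V_j^{t-1},

where the fresh new-word token models a birth.  Each candidate c gets a score

    wscore(c) = Σ_{j holds c} w_ij / |V_j^{t-1}|      (existing cognate)
    wscore(new word) = b · p_i,

a set v gets sscore(v) = Σ_{c∈v} wscore(c) − d·|v|², and the next set is drawn
with probability proportional to exp(sscore(v)).  The update is synchronous:
every node reads only the t−1 state.  A cognate that is absent from all nodes
is dead and can never revive, because candidates are built from surviving
sets only.

Sampling is exact.  The distribution factorises over set size:
P(v) ∝ exp(Σ_{c∈v} wscore(c)) · exp(−d|v|²), so the size k is drawn with
weight e_k(x₁..x_n)·exp(−dk²) where x_c = exp(wscore(c)) and e_k is the
elementary symmetric polynomial, and a k-subset is then drawn with
probability ∝ Π x_c by the standard sequential-inclusion recursion.  This
avoids enumerating the 2^n − 1 subsets; the enumerating
:func:`subset_distribution` is retained as a brute-force oracle for small
candidate pools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from random import Random
from typing import Iterable, Mapping, Sequence

import numpy as np

from .topology import InfluenceMatrix, SimParams, Topology, influence_weights

__all__ = [
    "NetworkState",
    "CandidateSet",
    "CognateRecord",
    "CognateRegistry",
    "SimulationResult",
    "candidate_set",
    "cognate_score",
    "set_score",
    "subset_distribution",
    "sample_subset",
    "step_network",
    "run_concept",
    "run_simulation",
    "ENUMERATION_CAP",
]

#: largest candidate pool for which subset_distribution enumerates the
#: 2^n - 1 non-empty subsets; beyond this only the factorized sampler runs.
ENUMERATION_CAP = 15


@dataclass
class NetworkState:
    """Snapshot of the network at step t: node id -> non-empty cognate set."""

    t: int
    V: dict[str, frozenset[int]]

    def copy(self) -> "NetworkState":
        return NetworkState(self.t, dict(self.V))


@dataclass(frozen=True)
class CandidateSet:
    """Candidate pool C_i^t for one node: surviving cognates plus one fresh
    new-word token (``new_word``), with wscores for every candidate."""

    node: str
    t: int
    cognates: frozenset[int]
    new_word: int
    scores: Mapping[int, float]


@dataclass
class CognateRecord:
    cognate_id: int
    concept: int
    birth_node: str | None  # None for the shared initial cognate
    birth_time: int
    death_time: int | None = None  # None while alive

    @property
    def alive(self) -> bool:
        return self.death_time is None


class CognateRegistry:
    """Birth/death ledger for every cognate of one concept.

    Each cognate id is born exactly once; ``death_time`` is the first step at
    which the cognate is held by no node, and a dead cognate never reappears.
    """

    def __init__(self, concept: int = 0):
        self.concept = concept
        self.records: dict[int, CognateRecord] = {}
        self._next_id = 0

    def peek_new_id(self) -> int:
        """The id a new word would get if born now (not yet allocated)."""
        return self._next_id

    def register_birth(self, node: str | None, time: int) -> int:
        cid = self._next_id
        self._next_id += 1
        self.records[cid] = CognateRecord(cid, self.concept, node, time)
        return cid

    def register_death(self, cognate_id: int, time: int) -> None:
        rec = self.records[cognate_id]
        if rec.death_time is not None:
            raise ValueError(f"cognate {cognate_id} already died at {rec.death_time}")
        rec.death_time = time

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, cid: int) -> CognateRecord:
        return self.records[cid]

    def __iter__(self):
        return iter(self.records.values())


@dataclass
class SimulationResult:
    """Outcome of a multi-concept run: per-concept final states and ledgers.

    ``final_topology`` includes nodes created by topology events; ``states``
    and ``registries`` are indexed by concept.
    """

    topology: Topology
    final_topology: Topology
    params: SimParams
    states: list[dict[str, frozenset[int]]]
    registries: list[CognateRegistry]

    @property
    def taxa(self) -> tuple[str, ...]:
        return self.final_topology.node_ids


# -- per-node scoring ------------------------------------------------------


def candidate_set(
    state: NetworkState,
    node: str,
    topology: Topology,
    registry: CognateRegistry,
    weights: InfluenceMatrix | None = None,
    params: SimParams | None = None,
) -> CandidateSet:
    """Build C_i^t = {new word} ∪ ⋃_{j∈{i}∪N_i} V_j^{t-1} with wscores.

    The new-word id is provisional (``registry.peek_new_id()``); it is
    materialized in the registry only if the sampled set contains it.
    """
    if node not in topology.node_ids:
        raise KeyError(f"node {node!r} absent from network")
    if weights is None:
        if params is None:
            raise ValueError("need either weights or params to score candidates")
        weights = influence_weights(topology, params.s)
    neigh = (node, *topology.neighbors(node))
    scores: dict[int, float] = {}
    row = weights[node]
    for j in neigh:
        vj = state.V[j]
        contrib = row[j] / len(vj)
        for c in vj:
            scores[c] = scores.get(c, 0.0) + contrib
    new_id = registry.peek_new_id()
    b = params.b if params is not None else 1.0
    scores[new_id] = b * topology.populations[node]
    return CandidateSet(
        node=node,
        t=state.t + 1,
        cognates=frozenset(scores),
        new_word=new_id,
        scores=scores,
    )


def cognate_score(
    c: int,
    node: str,
    state: NetworkState,
    weights: InfluenceMatrix,
    params: SimParams,
    topology: Topology,
    *,
    is_new_word: bool = False,
) -> float:
    """wscore of a single candidate cognate for one node.

    For an existing cognate this sums w_ij / |V_j^{t-1}| over the nodes j in
    {i} ∪ N_i that held c at t−1; for the new word it is b·p_i.
    """
    if is_new_word:
        return params.b * topology.populations[node]
    total = 0.0
    found = False
    row = weights[node]
    for j in (node, *topology.neighbors(node)):
        vj = state.V[j]
        if c in vj:
            total += row[j] / len(vj)
            found = True
    if not found:
        raise ValueError(f"cognate {c} is not a candidate for node {node!r}")
    return total


def set_score(v: Iterable[int], scores: Mapping[int, float], d: float) -> float:
    """sscore(v) = Σ_{c∈v} (wscore(c) − d·|v|) = Σ wscore − d·|v|²."""
    v = list(v)
    if not v:
        raise ValueError("cognate set must be non-empty")
    size = len(v)
    return sum(scores[c] for c in v) - d * size * size


def subset_distribution(
    scores: Mapping[int, float], d: float
) -> dict[frozenset[int], float]:
    """Exact law over all non-empty subsets, by brute-force enumeration.

    Normalized softmax of sscore over the 2^n − 1 non-empty subsets.  Raises
    for candidate pools above :data:`ENUMERATION_CAP`, signalling callers to
    use :func:`sample_subset`'s factorized path instead.
    """
    items = list(scores)
    n = len(items)
    if n == 0:
        raise ValueError("no candidates")
    if n > ENUMERATION_CAP:
        raise ValueError(
            f"{n} candidates exceed the enumeration cap of {ENUMERATION_CAP}"
        )
    subsets: list[frozenset[int]] = []
    sscores: list[float] = []
    for k in range(1, n + 1):
        for combo in combinations(items, k):
            subsets.append(frozenset(combo))
            sscores.append(sum(scores[c] for c in combo) - d * k * k)
    m = max(sscores)
    weights = [math.exp(x - m) for x in sscores]
    total = sum(weights)
    return {s: w / total for s, w in zip(subsets, weights)}


def _suffix_esp(x: Sequence[float]) -> list[list[float]]:
    """Tables E[i][k] = e_k(x_i, .., x_{n-1}) of elementary symmetric polys."""
    n = len(x)
    tables: list[list[float]] = [[] for _ in range(n + 1)]
    tables[n] = [1.0]
    for i in range(n - 1, -1, -1):
        prev = tables[i + 1]
        xi = x[i]
        cur = [1.0] * (len(prev) + 1)
        for k in range(1, len(cur)):
            cur[k] = (prev[k] if k < len(prev) else 0.0) + xi * prev[k - 1]
        tables[i] = cur
    return tables


def _sample_indices(ws: Sequence[float], d: float, rng: Random) -> list[int]:
    """Draw a non-empty index subset with P(v) ∝ exp(Σ ws[i] − d|v|²).

    Exact two-stage scheme: |v| = k is drawn with weight e_k(x)·exp(−dk²)
    where x_i = exp(ws[i]) (computed max-shifted for stability), then a
    k-subset with probability ∝ Π x_i via sequential inclusion.
    """
    n = len(ws)
    if n == 0:
        raise ValueError("no candidates")
    if n == 1:
        return [0]
    m = max(ws)
    x = [math.exp(w - m) for w in ws]  # all in (0, 1]
    esp = _suffix_esp(x)
    full = esp[0]
    # log weight of size k, up to a constant: log e_k(x̃) + k·m − d·k²
    logw = []
    for k in range(1, n + 1):
        ek = full[k]
        logw.append((math.log(ek) if ek > 0.0 else -math.inf) + k * m - d * k * k)
    top = max(logw)
    weights = [math.exp(v - top) for v in logw]
    r = rng.random() * sum(weights)
    k = n
    acc = 0.0
    for idx, wgt in enumerate(weights):
        acc += wgt
        if r <= acc:
            k = idx + 1
            break
    chosen: list[int] = []
    rem = k
    for i in range(n):
        if rem == 0:
            break
        if n - i == rem:  # must take everything left
            chosen.extend(range(i, n))
            break
        p_incl = x[i] * esp[i + 1][rem - 1] / esp[i][rem]
        if rng.random() < p_incl:
            chosen.append(i)
            rem -= 1
    return chosen


def sample_subset(
    scores: Mapping[int, float], d: float, rng: Random
) -> frozenset[int]:
    """Draw one non-empty cognate set, distributed exactly as
    :func:`subset_distribution` but without enumerating the power set."""
    items = list(scores)
    idx = _sample_indices([scores[c] for c in items], d, rng)
    return frozenset(items[i] for i in idx)


# -- network updates -------------------------------------------------------


class _StepContext:
    """Pre-resolved per-node influence rows for a fixed topology."""

    __slots__ = ("order", "infl", "new_scores", "d")

    def __init__(self, topology: Topology, weights: InfluenceMatrix, params: SimParams):
        self.order = topology.node_ids
        self.infl: dict[str, list[tuple[str, float]]] = {}
        self.new_scores: dict[str, float] = {}
        for i in self.order:
            row = weights[i]
            self.infl[i] = [(i, row[i])] + [
                (j, row[j]) for j in topology.neighbors(i)
            ]
            self.new_scores[i] = params.b * topology.populations[i]
        self.d = params.d


def _step(
    state: NetworkState,
    ctx: _StepContext,
    registry: CognateRegistry,
    rng: Random,
    alive: set[int],
) -> NetworkState:
    t = state.t + 1
    V = state.V
    sizes = {j: len(V[j]) for j in ctx.order}
    new_V: dict[str, frozenset[int]] = {}
    d = ctx.d
    for i in ctx.order:
        scores: dict[int, float] = {}
        for j, wij in ctx.infl[i]:
            contrib = wij / sizes[j]
            for c in V[j]:
                if c in scores:
                    scores[c] += contrib
                else:
                    scores[c] = contrib
        new_id = registry.peek_new_id()
        scores[new_id] = ctx.new_scores[i]
        items = list(scores)
        chosen = _sample_indices([scores[c] for c in items], d, rng)
        picked = frozenset(items[k] for k in chosen)
        if new_id in picked:
            registry.register_birth(i, t)
            alive.add(new_id)
        new_V[i] = picked
    present: set[int] = set()
    for v in new_V.values():
        present.update(v)
    for cid in alive - present:
        registry.register_death(cid, t)
    alive.intersection_update(present)
    return NetworkState(t, new_V)


def step_network(
    state: NetworkState,
    topology: Topology,
    weights: InfluenceMatrix,
    registry: CognateRegistry,
    params: SimParams,
    rng: Random,
) -> NetworkState:
    """One synchronous update: every node samples its next set from
    candidates built exclusively from the t−1 snapshot; deaths are recorded
    for cognates absent from all nodes afterwards."""
    ctx = _StepContext(topology, weights, params)
    alive = {rec.cognate_id for rec in registry if rec.alive}
    return _step(state, ctx, registry, rng, alive)


def run_concept(
    topology: Topology,
    params: SimParams,
    rng: Random,
    concept: int = 0,
) -> tuple[dict[str, frozenset[int]], CognateRegistry]:
    """Simulate one concept for T steps and return (final sets, ledger).

    All nodes start from a single shared cognate.  Topology events fire on
    the snapshot at their step: the new node copies the source's current
    cognate set and joins every later update.
    """
    registry = CognateRegistry(concept)
    root = registry.register_birth(None, 0)
    state = NetworkState(0, {n: frozenset((root,)) for n in topology.node_ids})
    alive = {root}

    current = topology
    weights = influence_weights(current, params.s)
    ctx = _StepContext(current, weights, params)
    pending = list(topology.events)

    for t in range(1, params.T + 1):
        state = _step(state, ctx, registry, rng, alive)
        while pending and pending[0].time == t:
            ev = pending.pop(0)
            current = current.with_event_applied(ev)
            state.V[ev.target] = state.V[ev.source]
            weights = influence_weights(current, params.s)
            ctx = _StepContext(current, weights, params)
    return state.V, registry


def run_simulation(topology: Topology, params: SimParams) -> SimulationResult:
    """Run all concepts independently and collect their final snapshots.

    Concepts use independent RNG substreams spawned from ``params.seed``, so
    the result is reproducible and independent of evaluation order.
    """
    seeds = np.random.SeedSequence(params.seed).generate_state(
        params.n_concepts, np.uint32
    )
    states: list[dict[str, frozenset[int]]] = []
    registries: list[CognateRegistry] = []
    final_topo = topology
    for ev in topology.events:
        if ev.time <= params.T:
            final_topo = final_topo.with_event_applied(ev)
    for concept in range(params.n_concepts):
        rng = Random(int(seeds[concept]))
        final, registry = run_concept(topology, params, rng, concept)
        states.append(final)
        registries.append(registry)
    return SimulationResult(topology, final_topo, params, states, registries)
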