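"""Spatial contact networks for dialect simulation.

A network consists of dialect nodes (each with a population), undirected
weighted edges (each with a contact distance), and optional timed topology
change events.  The influence of node *j* on node *i* is

    w_ij = p_j / d_ij**2   if j is a neighbour of i,
    w_ii = s * p_i         (self-influence, scaled by the parameter s),
    w_ij = 0               otherwise,

so large populations are influential and influence decays quadratically with
distance.  Five named fixture networks (grid, star, two_stars, bottleneck,
colony) ship with the package as YAML configuration files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml

__all__ = [
    "Topology",
    "TopologyEvent",
    "SimParams",
    "InfluenceMatrix",
    "make_topology",
    "fixture_topology",
    "influence_weights",
    "load_config",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("grid", "star", "two_stars", "bottleneck", "colony")


@dataclass(frozen=True)
class TopologyEvent:
    """A timed change to the network: a new node copied from an existing one.

    The event fires once, on the snapshot at step ``time``: the target node is
    created with ``target_population`` and ``new_edges``, receives an exact
    copy of the source node's cognate sets, and participates in every update
    from step ``time + 1`` on.
    """

    time: int
    kind: str
    source: str
    target: str
    new_edges: tuple[tuple[str, float], ...]
    target_population: float

    def __post_init__(self) -> None:
        if self.kind != "copy_node":
            raise ValueError(f"unsupported event kind {self.kind!r}")
        if self.time < 1:
            raise ValueError("event time must be a step >= 1")
        if self.target_population <= 0:
            raise ValueError("target population must be positive")
        for neighbor, distance in self.new_edges:
            if distance <= 0:
                raise ValueError(
                    f"edge {self.target}-{neighbor}: distance must be positive"
                )


@dataclass(frozen=True)
class SimParams:
    """Scalar hyperparameters of the simulation.

    s : self-influence multiplier (w_ii = s * p_i), >= 0
    b : score of a brand-new word (wscore = b * p_i), >= 0
    d : cardinality cost, > 1; penalises cognate sets of size k by d*k**2
    T : number of discrete time steps
    n_concepts : number of independent basic-vocabulary concepts
    seed : master RNG seed
    """

    s: float
    b: float
    d: float
    T: int = 1000
    n_concepts: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("s must be nonnegative")
        if self.b < 0:
            raise ValueError("b must be nonnegative")
        if self.d <= 1:
            raise ValueError("d must be > 1")
        if self.T < 0:
            raise ValueError("T must be nonnegative")
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be positive")

    def with_overrides(self, **kwargs) -> "SimParams":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


@dataclass(frozen=True)
class Topology:
    """A validated spatial contact network.

    ``populations`` maps node id -> population p_i > 0; ``distances`` maps the
    unordered pair (i, j) (stored with i < j) -> d_ij > 0.  ``events`` are
    sorted by time.
    """

    node_ids: tuple[str, ...]
    populations: Mapping[str, float]
    distances: Mapping[tuple[str, str], float]
    events: tuple[TopologyEvent, ...] = ()

    @cached_property
    def _neighbor_map(self) -> dict[str, tuple[str, ...]]:
        m: dict[str, list[str]] = {n: [] for n in self.node_ids}
        for (i, j) in self.distances:
            m[i].append(j)
            m[j].append(i)
        return {n: tuple(sorted(v)) for n, v in m.items()}

    def neighbors(self, node: str) -> tuple[str, ...]:
        return self._neighbor_map[node]

    def distance(self, i: str, j: str) -> float:
        key = (i, j) if i < j else (j, i)
        return self.distances[key]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.node_ids:
            g.add_node(n, population=self.populations[n])
        for (i, j), dist in self.distances.items():
            g.add_edge(i, j, distance=dist)
        return g

    def with_event_applied(self, event: TopologyEvent) -> "Topology":
        """Return the grown topology after a copy_node event (structure only)."""
        if event.target in self.node_ids:
            raise ValueError(f"event target {event.target!r} already present")
        if event.source not in self.node_ids:
            raise ValueError(f"event source {event.source!r} not in network")
        nodes = [(n, self.populations[n]) for n in self.node_ids]
        nodes.append((event.target, event.target_population))
        edges = [(i, j, d) for (i, j), d in self.distances.items()]
        edges.extend((event.target, nb, d) for nb, d in event.new_edges)
        return make_topology(nodes, edges, events=())


def make_topology(
    nodes: Iterable[tuple[str, float]],
    edges: Iterable[tuple[str, str, float]],
    events: Iterable[TopologyEvent] = (),
) -> Topology:
    """Build and validate a :class:`Topology`.

    ``nodes`` is an iterable of (node_id, population); ``edges`` of
    (i, j, distance), undirected, one record per pair, no self-loops.
    """
    populations: dict[str, float] = {}
    order: list[str] = []
    for node_id, pop in nodes:
        node_id = str(node_id)
        if node_id in populations:
            raise ValueError(f"duplicate node id {node_id!r}")
        if pop <= 0:
            raise ValueError(f"node {node_id!r}: population must be positive")
        populations[node_id] = float(pop)
        order.append(node_id)

    distances: dict[tuple[str, str], float] = {}
    for i, j, dist in edges:
        i, j = str(i), str(j)
        if i == j:
            raise ValueError(f"self-loop on node {i!r} not allowed")
        for endpoint in (i, j):
            if endpoint not in populations:
                raise ValueError(f"edge endpoint {endpoint!r} is not a node")
        key = (i, j) if i < j else (j, i)
        if key in distances:
            raise ValueError(f"duplicate edge {key}")
        if dist <= 0:
            raise ValueError(f"edge {key}: distance must be positive")
        distances[key] = float(dist)

    events = tuple(sorted(events, key=lambda e: e.time))
    present = set(populations)
    for ev in events:
        if ev.target in present:
            raise ValueError(f"event target {ev.target!r} already in network")
        if ev.source not in present:
            raise ValueError(f"event source {ev.source!r} not in network")
        for neighbor, _ in ev.new_edges:
            if neighbor not in present and neighbor != ev.target:
                raise ValueError(f"event edge endpoint {neighbor!r} unknown")
        present.add(ev.target)

    return Topology(tuple(order), populations, distances, events)


class InfluenceMatrix:
    """Directed influence weights w_ij derived from populations and distances.

    Generally asymmetric: w[i][j] = p_j / d_ij**2 while w[j][i] = p_i / d_ij**2.
    """

    def __init__(self, weights: Mapping[str, Mapping[str, float]]):
        self._w = {i: dict(row) for i, row in weights.items()}

    def __getitem__(self, i: str) -> Mapping[str, float]:
        return self._w[i]

    def get(self, i: str, j: str) -> float:
        return self._w.get(i, {}).get(j, 0.0)

    def rows(self):
        return self._w.items()


def influence_weights(topology: Topology, s: float) -> InfluenceMatrix:
    """Compute the influence matrix for a topology and self-influence s."""
    if s < 0:
        raise ValueError("s must be nonnegative")
    w: dict[str, dict[str, float]] = {i: {} for i in topology.node_ids}
    for i in topology.node_ids:
        w[i][i] = s * topology.populations[i]
    for (i, j), dist in topology.distances.items():
        d2 = dist * dist
        w[i][j] = topology.populations[j] / d2
        w[j][i] = topology.populations[i] / d2
    return InfluenceMatrix(w)


# -- configuration ---------------------------------------------------------


def _parse_config(cfg: Mapping) -> tuple[Topology, SimParams]:
    nodes = [(n["id"], float(n["population"])) for n in cfg["nodes"]]
    edges = [(e["i"], e["j"], float(e["distance"])) for e in cfg.get("edges", [])]
    events = [
        TopologyEvent(
            time=int(ev["time"]),
            kind=ev.get("kind", "copy_node"),
            source=ev["source"],
            target=ev["target"],
            new_edges=tuple(
                (ne["neighbor"], float(ne["distance"])) for ne in ev["new_edges"]
            ),
            target_population=float(ev["target_population"]),
        )
        for ev in cfg.get("events", [])
    ]
    topo = make_topology(nodes, edges, events)
    p = cfg.get("params", {})
    params = SimParams(
        s=float(p.get("s", 1.0)),
        b=float(p.get("b", 1.0)),
        d=float(p.get("d", 3.0)),
        T=int(p.get("T", 1000)),
        n_concepts=int(p.get("n_concepts", 100)),
        seed=int(p.get("seed", 0)),
    )
    return topo, params


def load_config(path: str | Path) -> tuple[Topology, SimParams]:
    """Load a topology + parameters from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _parse_config(cfg)


def fixture_topology(name: str) -> tuple[Topology, SimParams]:
    """Return one of the five built-in networks with its hyperparameters.

    grid        3x3 lattice, equal populations       (s=4.0, b=1.0, d=3.0)
    star        one large centre, 8 peripheries      (s=2.0, b=0.1, d=3.0)
    two_stars   two centres, two shared nodes        (s=2.0, b=1.0, d=3.0)
    bottleneck  two clusters, one long bridge edge   (s=4.0, b=0.1, d=3.0)
    colony      node B copied from A at step 750     (s=4.0, b=0.1, d=3.0)
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("dialectsim").joinpath(f"fixtures/{name}.yaml")
    cfg = yaml.safe_load(ref.read_text())
    return _parse_config(cfg)
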