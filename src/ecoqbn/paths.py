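"""Disturbance-labelled state-transition graphs with cycles.

State-and-transition models describe ecosystems as a directed graph whose
nodes are vegetation/ecosystem states and whose edges are disturbance-driven
transitions (fire, thermokarst, permafrost aggradation, grazing...).  Unlike
a Bayesian network the graph may — and in intransitive systems does —
contain cycles: black spruce forest can return to black spruce forest
through a circuit of disturbances, just as rock-paper-scissors dominance
closes on itself.

Each edge carries a probability amplitude ``sqrt(p)·e^{iθ}``.  A path's
classical probability is the product of the squared edge magnitudes times
the initial-state probability; the quantum per-path value (each leg squared
separately) is provably identical, so interference appears only when
several paths between the same endpoints are superposed coherently:
``coherent_total = |Σ path amplitudes|²`` versus the classical
``Σ |path amplitude|²``.

Edge amplitudes are *possibility* weights, not rows of a stochastic matrix:
normalization over the label-matching out-edges happens at use time when a
disturbance sequence is applied.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .amplitude import Amplitude, Phase
from .errors import DomainError, GraphError, PathError, StrandedSequenceError


@dataclass(frozen=True)
class Edge:
    """A labelled transition with its probability amplitude."""

    source: str
    target: str
    label: str
    amplitude: Amplitude

    def __post_init__(self):
        if not (0.0 < self.amplitude.magnitude <= 1.0):
            raise DomainError(
                f"edge {self.source}->{self.target} [{self.label}]: amplitude "
                f"magnitude must be in (0, 1], got {self.amplitude.magnitude}"
            )

    @property
    def probability(self) -> float:
        return self.amplitude.magnitude**2


class TransitionGraph:
    """A directed multigraph of ecosystem states with disturbance-labelled,
    amplitude-weighted edges.  Parallel edges must carry distinct labels."""

    def __init__(self, states: Sequence[str], edges: Iterable[Edge]):
        self.states: tuple[str, ...] = tuple(str(s) for s in states)
        if len(set(self.states)) != len(self.states):
            raise GraphError(f"duplicate states in {self.states}")
        self.edges: tuple[Edge, ...] = tuple(edges)
        seen: set[tuple[str, str, str]] = set()
        for e in self.edges:
            if e.source not in self.states or e.target not in self.states:
                raise GraphError(
                    f"edge {e.source}->{e.target} references unknown state"
                )
            key = (e.source, e.target, e.label)
            if key in seen:
                raise GraphError(
                    f"parallel edges {e.source}->{e.target} must have "
                    f"distinct disturbance labels (duplicate {e.label!r})"
                )
            seen.add(key)
        self._out: dict[str, list[Edge]] = {s: [] for s in self.states}
        for e in self.edges:
            self._out[e.source].append(e)
        # deterministic traversal order everywhere downstream
        for s in self._out:
            self._out[s].sort(key=lambda e: (e.target, e.label))

    @classmethod
    def from_probabilities(
        cls,
        states: Sequence[str],
        edges: Iterable[tuple[str, str, str, float] | tuple[str, str, str, float, float]],
    ) -> "TransitionGraph":
        """Build from ``(source, target, label, p[, theta])`` tuples."""
        built = []
        for t in edges:
            src, dst, lab, p = t[0], t[1], t[2], float(t[3])
            theta = float(t[4]) if len(t) > 4 else 0.0
            built.append(Edge(src, dst, lab, Amplitude(math.sqrt(p), Phase(theta))))
        return cls(states, built)

    def out_edges(self, state: str, label: str | None = None) -> list[Edge]:
        if state not in self._out:
            raise GraphError(f"unknown state {state!r}")
        es = self._out[state]
        if label is not None:
            es = [e for e in es if e.label == label]
        return list(es)

    @property
    def labels(self) -> set[str]:
        return {e.label for e in self.edges}

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.states)
        for e in self.edges:
            g.add_edge(e.source, e.target, label=e.label, p=e.probability)
        return g


@dataclass(frozen=True)
class Path:
    """An ordered chain of edges: consecutive edges must connect."""

    steps: tuple[Edge, ...]

    def __post_init__(self):
        if not self.steps:
            raise PathError("a path needs at least one step")
        for a, b in zip(self.steps, self.steps[1:]):
            if a.target != b.source:
                raise PathError(
                    f"broken chain: step ends at {a.target!r} but next "
                    f"starts at {b.source!r}"
                )

    @property
    def start(self) -> str:
        return self.steps[0].source

    @property
    def end(self) -> str:
        return self.steps[-1].target

    @property
    def states(self) -> tuple[str, ...]:
        return (self.start,) + tuple(e.target for e in self.steps)

    @property
    def label_sequence(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.steps)

    def amplitude(self) -> complex:
        z = complex(1.0, 0.0)
        for e in self.steps:
            z *= e.amplitude.to_complex()
        return z

    def __len__(self):
        return len(self.steps)


def path_probability_classical(
    g: TransitionGraph, path: Path, initial: float = 1.0
) -> float:
    """``P(A→B→…) = P(A) · Π P(step)``: the classical product rule."""
    if not (0.0 <= initial <= 1.0):
        raise DomainError(f"initial probability must be in [0, 1], got {initial}")
    _require_in_graph(g, path)
    out = float(initial)
    for e in path.steps:
        out *= e.probability
    return out


def path_probability_quantum(
    g: TransitionGraph, path: Path, initial: Amplitude | complex = 1.0
) -> float:
    """Per-path quantum probability: product of squared leg-amplitude
    magnitudes.

    Because every leg is squared separately, this coincides exactly with
    :func:`path_probability_classical` at ``initial = |initial amplitude|²``
    for every phase assignment — single paths carry no interference.
    """
    z = initial.to_complex() if isinstance(initial, Amplitude) else complex(initial)
    return path_probability_classical(g, path, abs(z) ** 2)


def _require_in_graph(g: TransitionGraph, path: Path):
    edge_set = set(g.edges)
    for e in path.steps:
        if e not in edge_set:
            raise PathError(
                f"edge {e.source}->{e.target} [{e.label}] is not in the graph"
            )


def enumerate_paths(
    g: TransitionGraph,
    start: str,
    end: str,
    max_len: int,
    allow_repeated_edges: bool = False,
) -> list[Path]:
    """All edge sequences from ``start`` to ``end`` of length ≤ ``max_len``.

    States may be revisited, but by default no directed edge is traversed
    twice within one path, so each circuit is walked at most once;
    ``allow_repeated_edges=True`` lifts that (``max_len`` remains a hard
    cap).  Paths are returned in deterministic lexicographic order of their
    (target, label) edge keys.
    """
    if start not in g.states or end not in g.states:
        raise GraphError(f"unknown state(s): {start!r}, {end!r}")
    if max_len < 1:
        return []
    found: list[Path] = []

    def walk(state: str, steps: list[Edge], used: set[Edge]):
        if steps and state == end:
            found.append(Path(tuple(steps)))
        if len(steps) >= max_len:
            return
        for e in g.out_edges(state):
            if not allow_repeated_edges and e in used:
                continue
            steps.append(e)
            if not allow_repeated_edges:
                used.add(e)
            walk(e.target, steps, used)
            if not allow_repeated_edges:
                used.remove(e)
            steps.pop()

    walk(start, [], set())
    return found


@dataclass
class PathEnsemble:
    """A superposed bundle of paths between two endpoints.

    ``classical_total`` sums per-path probabilities; ``coherent_total``
    squares the coherent amplitude sum, so aligned-phase paths reinforce
    (up to ``(Σ|ψ|)²``) and opposed-phase paths cancel.
    """

    paths: list[Path] = field(default_factory=list)
    amplitudes: list[complex] = field(default_factory=list)
    classical_total: float = 0.0
    coherent_total: float = 0.0
    interference_term: float = 0.0
    mode: str = "coherent"

    @property
    def empty(self) -> bool:
        return not self.paths


def multipath_superposition(
    g: TransitionGraph,
    start: str,
    end: str,
    max_len: int,
    mode: str = "coherent",
) -> PathEnsemble:
    """Superpose every start→end path within ``max_len`` steps.

    In ``classical`` mode the coherent total simply repeats the classical
    sum (no interference); in ``coherent`` mode the paths are added at the
    amplitude level first.  No path at all yields an empty ensemble, not an
    error.
    """
    if mode not in ("classical", "coherent"):
        raise DomainError(f"mode must be 'classical' or 'coherent', got {mode!r}")
    paths = enumerate_paths(g, start, end, max_len)
    if not paths:
        return PathEnsemble(mode=mode)
    amps = [p.amplitude() for p in paths]
    classical = float(sum(abs(z) ** 2 for z in amps))
    if mode == "classical":
        coherent = classical
    else:
        coherent = float(abs(sum(amps)) ** 2)
    return PathEnsemble(
        paths=paths,
        amplitudes=amps,
        classical_total=classical,
        coherent_total=coherent,
        interference_term=coherent - classical,
        mode=mode,
    )


def find_intransitive_circuits(
    g: TransitionGraph, max_len: int
) -> list[Path]:
    """All directed circuits of length ≤ ``max_len``, canonicalized to start
    at their lexicographically smallest state.

    A circuit through the full state cycle is the signature of an
    intransitive system (rock→scissors→paper→rock; spruce→bog→shrubland→
    spruce).  A DAG returns an empty list.
    """
    if max_len < 2:
        max_len = max(max_len, 1)
    circuits: list[Path] = []
    nxg = g.to_networkx()
    for cyc in nx.simple_cycles(nxg, length_bound=max_len):
        # canonical rotation: start at the smallest state name
        k = min(range(len(cyc)), key=lambda i: cyc[i])
        nodes = cyc[k:] + cyc[:k]
        hops = list(zip(nodes, nodes[1:] + nodes[:1]))
        # expand parallel-edge label choices deterministically
        options = [g.out_edges(a) for a, _ in hops]
        options = [
            [e for e in opts if e.target == b]
            for opts, (_, b) in zip(options, hops)
        ]
        for combo in itertools.product(*options):
            circuits.append(Path(tuple(combo)))
    circuits.sort(key=lambda p: (len(p), p.states, p.label_sequence))
    return circuits


@dataclass
class SequenceOutcome:
    """End-state distribution after a disturbance sequence, plus whether
    permuting the sequence would have changed it."""

    distribution: dict[str, float]
    sequence: tuple[str, ...]
    order_sensitive: bool | None = None


def apply_disturbance_sequence(
    g: TransitionGraph,
    start: str,
    labels: Sequence[str],
    check_order: bool = False,
    max_permutations: int = 720,
) -> SequenceOutcome:
    """Propagate probability mass through edges matching each disturbance
    label in order.

    From each occupied state the mass branches over the label-matching
    out-edges, weighted by their squared magnitudes normalized among those
    matches; a state with no matching out-edge keeps its mass (the
    disturbance cannot transition it).  If *no* occupied state has a
    matching edge the sequence is stranded and the reachable prefix is
    reported.  ``check_order=True`` additionally applies every distinct
    permutation of the labels and flags whether any end distribution
    differs — disturbance order matters in noncommutative systems.
    """
    if start not in g.states:
        raise GraphError(f"unknown start state {start!r}")
    known = g.labels
    for lab in labels:
        if lab not in known:
            raise GraphError(f"unknown disturbance label {lab!r}")

    dist = _propagate(g, start, labels)
    out = SequenceOutcome(dist, tuple(labels))
    if check_order:
        perms = set(itertools.permutations(labels))
        if len(perms) > max_permutations:
            raise DomainError(
                f"{len(perms)} permutations exceed the cap {max_permutations}"
            )
        sensitive = False
        for perm in perms:
            try:
                alt = _propagate(g, start, perm)
            except StrandedSequenceError:
                sensitive = True
                break
            if any(abs(alt.get(s, 0.0) - dist.get(s, 0.0)) > 1e-12 for s in g.states):
                sensitive = True
                break
        out.order_sensitive = sensitive
    return out


def _propagate(
    g: TransitionGraph, start: str, labels: Sequence[str]
) -> dict[str, float]:
    mass: dict[str, float] = {start: 1.0}
    for i, lab in enumerate(labels):
        nxt: dict[str, float] = {}
        moved = False
        for state, m in mass.items():
            matches = g.out_edges(state, lab)
            if not matches:
                nxt[state] = nxt.get(state, 0.0) + m
                continue
            moved = True
            weights = np.asarray([e.probability for e in matches])
            weights = weights / weights.sum()
            for e, w in zip(matches, weights):
                nxt[e.target] = nxt.get(e.target, 0.0) + m * float(w)
        if not moved:
            raise StrandedSequenceError(
                f"disturbance {lab!r} (step {i + 1}) applies to no occupied "
                f"state; reachable prefix: {list(labels[:i])}",
                labels[:i],
                mass,
            )
        mass = nxt
    return {s: mass.get(s, 0.0) for s in g.states if mass.get(s, 0.0) > 0.0}
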