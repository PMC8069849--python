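"""Quantum-like Bayesian networks: structure, tables, and inference.

A network is a DAG of nodes, each carrying a conditional *amplitude* table:
for every configuration of its parents, a vector of complex amplitudes over
the node's states whose squared magnitudes sum to 1.  Squaring every entry
recovers an ordinary Bayesian network; the phases are extra degrees of
freedom that create interference between the hidden-variable paths summed
out during inference.

Inference is exact enumeration over joint assignments (the published
ecological examples are tiny; the enumeration cap is configurable).  Two
modes are exposed:

``classical``
    Sums squared magnitudes — textbook enumeration inference.

``coherent``
    For each query state, the hidden assignments contribute a bundle of
    joint amplitudes.  The query state's mass is its classical mass
    multiplied by the bundle's *coherence visibility* ``|Σψ|²/(Σ|ψ|)²``,
    then renormalized over query states.  When all pairwise phase
    differences inside every bundle vanish (in particular for a phase-free
    network) the visibility is 1 and the two modes coincide exactly; fully
    destructive bundles are extinguished.

Order-sensitive evidence lives in :func:`sequential_condition`: findings are
applied as projective measurements on the joint state vector, one at a time.
Plain findings are diagonal projectors and commute; a finding measured in a
rotated basis (a Givens rotation of a two-state node) does not commute with
findings on correlated nodes, which realizes noncommutative evidence
ordering.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .amplitude import (
    Amplitude,
    Basis,
    InterferenceReport,
    NORM_TOL,
    StateVector,
    ZERO_PROB,
    coherence_visibility,
)
from .errors import (
    DomainError,
    MeasurementError,
    NetworkError,
)

#: Default cap on the joint-state-space size for exact enumeration
#: (20 binary-equivalent nodes).
MAX_JOINT_STATES = 2**20


class CondAmplitudeTable:
    """Per-parent-configuration amplitude vectors — the quantum analogue of
    a conditional probability table.

    ``rows`` maps a tuple of parent state names (in parent order; the empty
    tuple for a root node) to a complex vector over the node's states.
    """

    def __init__(
        self,
        rows: Mapping[tuple[str, ...], Sequence[complex | Amplitude]],
    ):
        self.rows: dict[tuple[str, ...], np.ndarray] = {}
        for cfg, amps in rows.items():
            key = tuple(str(s) for s in cfg)
            vec = np.asarray(
                [
                    a.to_complex() if isinstance(a, Amplitude) else complex(a)
                    for a in amps
                ],
                dtype=complex,
            )
            self.rows[key] = vec

    @classmethod
    def from_probabilities(
        cls,
        rows: Mapping[tuple[str, ...], Sequence[float]],
        phases: Mapping[tuple[str, ...], Sequence[float]] | None = None,
    ) -> "CondAmplitudeTable":
        """Square-root embed classical rows, with optional per-entry phases."""
        out: dict[tuple[str, ...], list[complex]] = {}
        for cfg, probs in rows.items():
            ths = phases.get(cfg, [0.0] * len(probs)) if phases else [0.0] * len(probs)
            out[cfg] = [
                math.sqrt(float(p)) * complex(math.cos(t), math.sin(t))
                for p, t in zip(probs, ths)
            ]
        return cls(out)

    def row(self, cfg: tuple[str, ...]) -> np.ndarray:
        try:
            return self.rows[cfg]
        except KeyError:
            raise NetworkError(
                f"no table row for parent configuration {cfg!r}"
            ) from None


@dataclass
class QNode:
    """A network node: named states, ordered parents, and an amplitude table.

    ``basis_rotation`` (radians) is the default measurement-basis rotation
    used when this node appears as ordered evidence; it only applies to
    two-state nodes and defaults to 0 (the plain, commuting basis).
    """

    name: str
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()
    table: CondAmplitudeTable = field(default_factory=lambda: CondAmplitudeTable({}))
    basis_rotation: float = 0.0

    def __post_init__(self):
        self.states = tuple(str(s) for s in self.states)
        self.parents = tuple(str(p) for p in self.parents)
        if len(self.states) < 2:
            raise NetworkError(f"node {self.name!r} needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise NetworkError(f"node {self.name!r} has duplicate states")

    @property
    def basis(self) -> Basis:
        return Basis(self.states)


@dataclass(frozen=True)
class Finding:
    """One observed (node, state) pair, optionally measured in a rotated
    basis (radians; overrides the node's default when not None)."""

    node: str
    state: str
    rotation: float | None = None


class OrderedEvidence:
    """An ordered list of findings; the order is significant and preserved.

    Classical Bayesian conditioning is commutative; this container exists
    because projective measurement in rotated bases is not.
    """

    def __init__(
        self,
        findings: Iterable[tuple[str, str] | Finding],
        rotations: Mapping[str, float] | None = None,
    ):
        items: list[Finding] = []
        for f in findings:
            if not isinstance(f, Finding):
                f = Finding(str(f[0]), str(f[1]))
            if rotations and f.rotation is None and f.node in rotations:
                f = Finding(f.node, f.state, float(rotations[f.node]))
            items.append(f)
        names = [f.node for f in items]
        if len(set(names)) != len(names):
            raise DomainError(f"a node appears twice in evidence: {names}")
        self.findings: tuple[Finding, ...] = tuple(items)

    def reversed(self) -> "OrderedEvidence":
        return OrderedEvidence(tuple(reversed(self.findings)))

    def as_dict(self) -> dict[str, str]:
        return {f.node: f.state for f in self.findings}

    def __len__(self):
        return len(self.findings)

    def __iter__(self):
        return iter(self.findings)


class QuantumNetwork:
    """A collection of nodes whose parent lists imply the edge set.

    Construction only requires unique node names; run
    :func:`validate_network` for a full report, or any inference routine,
    which insists on validity first.  Cyclic structures are rejected here —
    cyclic ecological systems are the province of the transition-graph
    module.
    """

    def __init__(self, nodes: Iterable[QNode]):
        self.nodes: dict[str, QNode] = {}
        for n in nodes:
            if n.name in self.nodes:
                raise NetworkError(f"duplicate node name {n.name!r}")
            self.nodes[n.name] = n

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(self.nodes)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for n in self.nodes.values():
            for p in n.parents:
                g.add_edge(p, n.name)
        return g

    def topological_order(self) -> list[str]:
        g = self.graph()
        try:
            return list(nx.lexicographical_topological_sort(g))
        except nx.NetworkXUnfeasible:
            raise NetworkError(
                "network contains a cycle; Bayesian networks must be acyclic "
                "— model cyclic (intransitive) systems with a TransitionGraph"
            ) from None

    def require_valid(self):
        report = validate_network(self)
        if not report.ok:
            raise NetworkError(
                "invalid network:\n  " + "\n  ".join(report.issues)
            )

    def joint_size(self) -> int:
        size = 1
        for n in self.nodes.values():
            size *= len(n.states)
        return size


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self):
        return self.ok


def validate_network(net: QuantumNetwork) -> ValidationReport:
    """Collect every structural and normalization violation in a network.

    The report is empty iff the network is valid; nothing raises, so file
    readers can surface all problems at once.
    """
    issues: list[str] = []
    for node in net.nodes.values():
        for p in node.parents:
            if p not in net.nodes:
                issues.append(
                    f"node {node.name!r}: parent {p!r} does not exist"
                )
        if node.basis_rotation != 0.0 and len(node.states) != 2:
            issues.append(
                f"node {node.name!r}: basis rotation is only defined for "
                "two-state nodes"
            )
        expected = [
            cfg
            for cfg in itertools.product(
                *(net.nodes[p].states for p in node.parents if p in net.nodes)
            )
        ]
        if any(p not in net.nodes for p in node.parents):
            continue  # row check meaningless with dangling parents
        seen = set(node.table.rows)
        for cfg in expected:
            if cfg not in seen:
                issues.append(
                    f"node {node.name!r}: missing table row for parent "
                    f"configuration {cfg!r}"
                )
        for cfg in seen - set(expected):
            issues.append(
                f"node {node.name!r}: unexpected table row {cfg!r}"
            )
        for cfg in expected:
            if cfg not in node.table.rows:
                continue
            vec = node.table.rows[cfg]
            if len(vec) != len(node.states):
                issues.append(
                    f"node {node.name!r}, row {cfg!r}: {len(vec)} amplitudes "
                    f"for {len(node.states)} states"
                )
                continue
            mass = float(np.sum(np.abs(vec) ** 2))
            if abs(mass - 1.0) > NORM_TOL:
                issues.append(
                    f"node {node.name!r}, row {cfg!r}: squared magnitudes "
                    f"sum to {mass:.6g}, not 1"
                )
    g = net.graph()
    if net.nodes and not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        path = " -> ".join(e[0] for e in cyc) + " -> " + cyc[-1][1]
        issues.append(
            f"parent cycle {path}: Bayesian networks must be acyclic; "
            "model cyclic state transitions with a TransitionGraph instead"
        )
    return ValidationReport(issues)


def _check_assignment(net: QuantumNetwork, assignment: Mapping[str, str]):
    missing = [n for n in net.nodes if n not in assignment]
    if missing:
        raise DomainError(f"assignment missing nodes {missing}")
    for name, state in assignment.items():
        node = net.nodes.get(name)
        if node is None:
            raise DomainError(f"assignment names unknown node {name!r}")
        if state not in node.states:
            raise DomainError(
                f"node {name!r} has no state {state!r} (states: {node.states})"
            )


def joint_amplitude(
    net: QuantumNetwork, assignment: Mapping[str, str]
) -> Amplitude:
    """Product of the complex table entries along a full assignment.

    With all phases zero this is ``sqrt`` of the classical joint; in general
    the phase of the product is the sum of the entry phases.
    """
    _check_assignment(net, assignment)
    z = complex(1.0, 0.0)
    for name in net.topological_order():
        node = net.nodes[name]
        cfg = tuple(assignment[p] for p in node.parents)
        row = node.table.row(cfg)
        z *= row[node.states.index(assignment[name])]
    return Amplitude.from_complex(z)


def classical_joint(
    net: QuantumNetwork, assignment: Mapping[str, str]
) -> float:
    """Classical joint probability: product of squared entry magnitudes."""
    a = joint_amplitude(net, assignment)
    return a.magnitude**2


def _assignments(net: QuantumNetwork, order: Sequence[str]):
    state_lists = [net.nodes[n].states for n in order]
    for combo in itertools.product(*state_lists):
        yield dict(zip(order, combo))


def _joint_amp_raw(
    net: QuantumNetwork, order: Sequence[str], assignment: Mapping[str, str]
) -> complex:
    z = complex(1.0, 0.0)
    for name in order:
        node = net.nodes[name]
        cfg = tuple(assignment[p] for p in node.parents)
        z *= node.table.row(cfg)[node.states.index(assignment[name])]
    return z


@dataclass
class Posterior:
    """A posterior distribution over one node's states, with the per-state
    interference bookkeeping from coherent inference."""

    node: str
    states: tuple[str, ...]
    probabilities: np.ndarray
    mode: str
    interference: dict[str, InterferenceReport]

    def __getitem__(self, state: str) -> float:
        return float(self.probabilities[self.states.index(state)])

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.states, self.probabilities)}

    def dominant_state(self) -> str:
        # lowest ordinal wins exact ties
        return self.states[int(np.argmax(self.probabilities))]


def posterior(
    net: QuantumNetwork,
    query: str,
    evidence: OrderedEvidence | Iterable[tuple[str, str]] | None = None,
    mode: str = "classical",
    max_joint_states: int = MAX_JOINT_STATES,
) -> Posterior:
    """Exact-enumeration posterior of ``query`` given findings.

    Evidence here is an unordered set of plain (diagonal-basis) findings;
    rotated measurement bases and order effects are handled by
    :func:`sequential_condition`.  Zero-probability evidence raises
    :class:`MeasurementError`.
    """
    if mode not in ("classical", "coherent"):
        raise DomainError(f"mode must be 'classical' or 'coherent', got {mode!r}")
    net.require_valid()
    if net.joint_size() > max_joint_states:
        raise NetworkError(
            f"joint state space of {net.joint_size()} exceeds the exact-"
            f"enumeration cap {max_joint_states}"
        )
    if query not in net.nodes:
        raise DomainError(f"unknown query node {query!r}")
    if evidence is None:
        evidence = OrderedEvidence([])
    elif not isinstance(evidence, OrderedEvidence):
        evidence = OrderedEvidence(evidence)
    ev = {}
    for f in evidence:
        if f.node == query:
            raise DomainError(f"evidence on the query node {query!r}")
        if f.node not in net.nodes:
            raise DomainError(f"evidence names unknown node {f.node!r}")
        if f.state not in net.nodes[f.node].states:
            raise DomainError(
                f"node {f.node!r} has no state {f.state!r}"
            )
        rot = f.rotation if f.rotation is not None else net.nodes[f.node].basis_rotation
        if rot:
            raise DomainError(
                f"evidence on {f.node!r} uses a rotated measurement basis; "
                "posterior() only supports plain findings — use "
                "sequential_condition() for order-sensitive rotated evidence"
            )
        ev[f.node] = f.state

    order = net.topological_order()
    qnode = net.nodes[query]
    bundles: dict[str, list[complex]] = {s: [] for s in qnode.states}
    for assignment in _assignments(net, order):
        if any(assignment[n] != s for n, s in ev.items()):
            continue
        bundles[assignment[query]].append(_joint_amp_raw(net, order, assignment))

    classical_mass = {
        s: float(np.sum(np.abs(np.asarray(amps, dtype=complex)) ** 2)) if amps else 0.0
        for s, amps in bundles.items()
    }
    total_classical = sum(classical_mass.values())
    if total_classical <= ZERO_PROB:
        raise MeasurementError(
            f"evidence {ev!r} has zero probability; cannot condition on an "
            "impossible event"
        )

    reports: dict[str, InterferenceReport] = {}
    if mode == "classical":
        masses = classical_mass
        for s in qnode.states:
            m = classical_mass[s]
            reports[s] = InterferenceReport(m, m, 0.0)
    else:
        masses = {}
        for s in qnode.states:
            amps = bundles[s]
            vis = coherence_visibility(amps) if amps else 1.0
            m = classical_mass[s] * vis
            masses[s] = m
            reports[s] = InterferenceReport(
                classical_mass[s], m, m - classical_mass[s]
            )
    total = sum(masses.values())
    if total <= ZERO_PROB:
        raise MeasurementError(
            "coherent interference extinguished every query state; the "
            "posterior is undefined"
        )
    probs = np.asarray([masses[s] / total for s in qnode.states])
    return Posterior(query, qnode.states, probs, mode, reports)


def joint_basis(net: QuantumNetwork) -> tuple[Basis, list[str]]:
    """Basis over all full assignments, labelled ``n1=s1,n2=s2,...`` in
    topological node order.  Returns (basis, node order)."""
    order = net.topological_order()
    names = [
        ",".join(f"{n}={assignment[n]}" for n in order)
        for assignment in _assignments(net, order)
    ]
    return Basis(names), order


def joint_state_vector(net: QuantumNetwork) -> tuple[StateVector, list[str]]:
    """The network's full wave function over the joint-assignment basis."""
    net.require_valid()
    basis, order = joint_basis(net)
    amps = [
        _joint_amp_raw(net, order, assignment)
        for assignment in _assignments(net, order)
    ]
    return StateVector.renormalized(basis, amps), order


def _rotation_matrix(phi: float) -> np.ndarray:
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s], [s, c]])


@dataclass
class SequentialResult:
    """Outcome of ordered projective conditioning.

    ``regime`` is ``"joint"`` when every finding used the plain diagonal
    basis (the final state lives on the joint-assignment basis) or
    ``"shared"`` when a rotated finding switched the engine to the shared
    question space (the final state lives on the reference node's
    two-state basis).  ``marginal(node)`` gives the Born distribution of a
    node's question in either regime.
    """

    state: StateVector
    regime: str
    _net: "QuantumNetwork"
    _reference: str | None = None

    def marginal(self, node: str) -> dict[str, float]:
        if self.regime == "joint":
            return marginal_from_joint(self.state, self._net, node)
        qnode = self._net.nodes.get(node)
        if qnode is None:
            raise DomainError(f"unknown node {node!r}")
        if len(qnode.states) != 2:
            raise DomainError(
                "shared-space marginals are defined for two-state nodes only"
            )
        u = _rotation_matrix(qnode.basis_rotation)
        out = {}
        for k, s in enumerate(qnode.states):
            b = u[:, k].astype(complex)
            out[s] = float(abs(np.vdot(b, self.state.vector)) ** 2)
        return out


def sequential_condition(
    net: QuantumNetwork,
    evidence: OrderedEvidence | Iterable[tuple[str, str]],
) -> SequentialResult:
    """Apply findings as projective measurements, collapsing after each, in
    the given order.

    Plain findings are diagonal projectors on the joint-assignment state
    vector; operators on distinct nodes commute, so any order of plain
    findings yields the same final vector — the classical, commutative
    regime.

    A finding whose node carries a measurement rotation declares its
    question *incompatible* with the others.  Incompatible questions cannot
    be orthogonal tensor factors (operators on different factors always
    commute); following the standard quantum-cognition construction they
    are instead measured in one shared two-state space, each node's
    projectors Givens-rotated by its angle ``[cosφ, −sinφ; sinφ, cosφ]``
    relative to the reference basis.  There rotated projectors genuinely
    fail to commute and the evidence order changes the outcome.  In the
    shared regime every measured node must have two states; the reference
    node (earliest measured node in topological order — stable under
    reordering of the findings) supplies the basis labels and the initial
    state, the square-root embedding of its prior marginal.
    """
    if not isinstance(evidence, OrderedEvidence):
        evidence = OrderedEvidence(evidence)
    net.require_valid()
    rotations: dict[str, float] = {}
    for f in evidence:
        if f.node not in net.nodes:
            raise DomainError(f"evidence names unknown node {f.node!r}")
        node = net.nodes[f.node]
        if f.state not in node.states:
            raise DomainError(f"node {f.node!r} has no state {f.state!r}")
        rot = f.rotation if f.rotation is not None else node.basis_rotation
        rotations[f.node] = float(rot)

    if any(rotations.values()):
        return _sequential_shared(net, evidence, rotations)
    return _sequential_joint(net, evidence)


def _sequential_joint(
    net: QuantumNetwork, evidence: OrderedEvidence
) -> SequentialResult:
    order = net.topological_order()
    dims = [len(net.nodes[n].states) for n in order]
    psi_sv, _ = joint_state_vector(net)
    tensor = psi_sv.vector.reshape(dims)
    for step, f in enumerate(evidence, start=1):
        node = net.nodes[f.node]
        axis = order.index(f.node)
        k = node.states.index(f.state)
        keep = np.zeros(dims[axis])
        keep[k] = 1.0
        tensor = tensor * keep.reshape(
            [-1 if i == axis else 1 for i in range(len(dims))]
        )
        mass = float(np.sum(np.abs(tensor) ** 2))
        if mass <= ZERO_PROB:
            raise MeasurementError(
                f"finding {step} ({f.node}={f.state}) has zero probability "
                "given the preceding findings"
            )
        tensor = tensor / math.sqrt(mass)
    basis, _ = joint_basis(net)
    return SequentialResult(StateVector(basis, tensor.reshape(-1)), "joint", net)


def _sequential_shared(
    net: QuantumNetwork,
    evidence: OrderedEvidence,
    rotations: Mapping[str, float],
) -> SequentialResult:
    for f in evidence:
        if len(net.nodes[f.node].states) != 2:
            raise DomainError(
                f"rotated (incompatible) evidence requires two-state nodes; "
                f"{f.node!r} has {len(net.nodes[f.node].states)} states"
            )
    order = net.topological_order()
    measured = [f.node for f in evidence]
    reference = min(measured, key=order.index)
    ref_node = net.nodes[reference]
    prior = posterior(net, reference, None, mode="classical").probabilities
    psi = np.sqrt(prior).astype(complex)
    for step, f in enumerate(evidence, start=1):
        node = net.nodes[f.node]
        k = node.states.index(f.state)
        b = _rotation_matrix(rotations[f.node])[:, k].astype(complex)
        amp = np.vdot(b, psi)
        p = float(abs(amp) ** 2)
        if p <= ZERO_PROB:
            raise MeasurementError(
                f"finding {step} ({f.node}={f.state}) has zero probability "
                "given the preceding findings"
            )
        psi = b * (amp / abs(amp))
    return SequentialResult(
        StateVector(ref_node.basis, psi), "shared", net, reference
    )


def marginal_from_joint(
    psi: StateVector, net: QuantumNetwork, node: str
) -> dict[str, float]:
    """Born-rule marginal of one node from a joint-basis state vector."""
    if node not in net.nodes:
        raise DomainError(f"unknown node {node!r}")
    order = net.topological_order()
    dims = [len(net.nodes[n].states) for n in order]
    probs = np.abs(psi.vector.reshape(dims)) ** 2
    axis = order.index(node)
    marg = probs.sum(axis=tuple(i for i in range(len(dims)) if i != axis))
    return {s: float(p) for s, p in zip(net.nodes[node].states, marg)}


def information_gain(
    net: QuantumNetwork,
    evidence: OrderedEvidence | Iterable[tuple[str, str]] | tuple[str, str],
    query: str,
) -> float:
    """Kullback–Leibler divergence (nats) of the posterior after the
    finding(s) from the prior marginal of ``query``.

    A gain of exactly 0 certifies solution-incompleteness for that finding:
    observing it conveys no information about the query's distribution.
    """
    if (
        isinstance(evidence, tuple)
        and len(evidence) == 2
        and all(isinstance(x, str) for x in evidence)
    ):
        evidence = [evidence]
    if not isinstance(evidence, OrderedEvidence):
        evidence = OrderedEvidence(evidence)
    prior = posterior(net, query, None, mode="classical").probabilities
    post = posterior(net, query, evidence, mode="classical").probabilities
    gain = 0.0
    for p, q in zip(post, prior):
        if p > 0.0:
            if q <= 0.0:
                raise MeasurementError(
                    "posterior support outside prior support"
                )
            gain += float(p) * math.log(float(p) / float(q))
    return max(gain, 0.0)
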