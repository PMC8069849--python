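"""Executable example systems: bat habitat, roshambo, and the boreal
spruce cycle, plus random-network generators for property testing.

Only a handful of numbers in these examples are published: the riparian
prior of 0.1 for the yellow-winged bat, the deterministic rules of
rock-paper-scissors, and the three-state boreal circuit
spruce → bog (thermokarst) → shrubland (permafrost/peat aggradation) →
spruce (aggradation + tree regeneration).  Every remaining conditional is a
fixed, documented placeholder so that worked examples are reproducible; the
``randomize``/``seed`` path replaces placeholders with seeded draws for
property tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError
from .network import CondAmplitudeTable, QNode, QuantumNetwork
from .paths import TransitionGraph

#: Published prior probability that riparian habitat is present.
RIPARIAN_PRIOR = 0.1

#: Documented placeholder conditionals for the bat network (the source
#: figure's cells are not printed in text form).
BAT_WOODLAND_PRIOR = 0.6
BAT_GOOD_GIVEN = {
    ("present", "present"): 0.9,
    ("present", "absent"): 0.65,
    ("absent", "present"): 0.35,
    ("absent", "absent"): 0.05,
}


def bat_network(
    riparian_prior: float = RIPARIAN_PRIOR,
    woodland_prior: float = BAT_WOODLAND_PRIOR,
    good_given: Mapping[tuple[str, str], float] | None = None,
    phases: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> QuantumNetwork:
    """Three-node habitat model for the yellow-winged bat.

    riparian (present/absent) and woodland_scrub_savanna (present/absent)
    are root nodes; habitat (good/poor) depends on both.  ``phases`` maps a
    node name to a single phase applied to its first-state amplitudes
    (simple one-knob interference for demos).  Passing ``rng`` replaces the
    placeholder conditionals (not the published riparian prior) with seeded
    draws.
    """
    good_given = dict(good_given or BAT_GOOD_GIVEN)
    if rng is not None:
        woodland_prior = float(rng.uniform(0.05, 0.95))
        good_given = {k: float(rng.uniform(0.05, 0.95)) for k in BAT_GOOD_GIVEN}
    phases = dict(phases or {})

    def row(p: float, theta: float) -> list[complex]:
        z = complex(math.cos(theta), math.sin(theta))
        return [math.sqrt(p) * z, math.sqrt(1.0 - p)]

    riparian = QNode(
        "riparian",
        ("present", "absent"),
        (),
        CondAmplitudeTable({(): row(riparian_prior, phases.get("riparian", 0.0))}),
    )
    woodland = QNode(
        "woodland_scrub_savanna",
        ("present", "absent"),
        (),
        CondAmplitudeTable(
            {(): row(woodland_prior, phases.get("woodland_scrub_savanna", 0.0))}
        ),
    )
    habitat = QNode(
        "habitat",
        ("good", "poor"),
        ("riparian", "woodland_scrub_savanna"),
        CondAmplitudeTable(
            {
                cfg: row(p, phases.get("habitat", 0.0))
                for cfg, p in good_given.items()
            }
        ),
    )
    return QuantumNetwork([riparian, woodland, habitat])


MOVES = ("rock", "paper", "scissors")
OUTCOMES = ("p1_wins", "p2_wins", "draw")


def _winner(m1: str, m2: str) -> str:
    if m1 == m2:
        return "draw"
    beats = {("rock", "scissors"), ("scissors", "paper"), ("paper", "rock")}
    return "p1_wins" if (m1, m2) in beats else "p2_wins"


def roshambo_network() -> QuantumNetwork:
    """The rock-paper-scissors network: two uniform move nodes and a
    deterministic outcome node.

    Intransitive (every move loses to some other) and solution-incomplete:
    observing a single move conveys zero information about the outcome.
    """
    u = [math.sqrt(1.0 / 3.0)] * 3
    p1 = QNode("player1", MOVES, (), CondAmplitudeTable({(): u}))
    p2 = QNode("player2", MOVES, (), CondAmplitudeTable({(): u}))
    rows = {}
    for m1 in MOVES:
        for m2 in MOVES:
            vec = [0.0] * len(OUTCOMES)
            vec[OUTCOMES.index(_winner(m1, m2))] = 1.0
            rows[(m1, m2)] = vec
    outcome = QNode(
        "outcome", OUTCOMES, ("player1", "player2"), CondAmplitudeTable(rows)
    )
    return QuantumNetwork([p1, p2, outcome])


def roshambo_dominance_graph() -> TransitionGraph:
    """The cyclic dominance digraph rock→scissors→paper→rock."""
    return TransitionGraph.from_probabilities(
        MOVES,
        [
            ("rock", "scissors", "beats", 1.0),
            ("scissors", "paper", "beats", 1.0),
            ("paper", "rock", "beats", 1.0),
        ],
    )


SPRUCE_STATES = ("black_spruce", "bog", "shrubland")
SPRUCE_EDGES = (
    ("black_spruce", "bog", "thermokarst"),
    ("bog", "shrubland", "aggradation"),
    ("shrubland", "black_spruce", "regeneration"),
)
#: Placeholder transition probability for each published circuit edge.
SPRUCE_EDGE_P = 0.7


def spruce_graph(
    edge_probability: float = SPRUCE_EDGE_P,
    phases: Mapping[str, float] | None = None,
) -> TransitionGraph:
    """The boreal three-state intransitive circuit.

    Black spruce forest → bog under permafrost thaw-collapse (thermokarst);
    bog → shrubland under permafrost/peat aggradation; shrubland → black
    spruce under further aggradation with tree regeneration.  ``phases``
    maps a disturbance label to an edge phase.
    """
    if not (0.0 < edge_probability <= 1.0):
        raise DomainError(
            f"edge probability must be in (0, 1], got {edge_probability}"
        )
    phases = dict(phases or {})
    return TransitionGraph.from_probabilities(
        SPRUCE_STATES,
        [
            (src, dst, lab, edge_probability, phases.get(lab, 0.0))
            for src, dst, lab in SPRUCE_EDGES
        ],
    )


def rotated_pair_network(rotation: float = math.pi / 4.0) -> QuantumNetwork:
    """The shipped two-node noncommutativity example.

    ``cause`` (0.7/0.3 prior) drives ``effect`` (0.9/0.1 and 0.2/0.8 rows);
    ``effect`` is measured in a basis rotated by ``rotation`` (default 45°).
    Presenting the two findings in opposite orders then yields measurably
    different final states — the projectors do not commute.
    """
    cause = QNode(
        "cause",
        ("on", "off"),
        (),
        CondAmplitudeTable({(): [math.sqrt(0.7), math.sqrt(0.3)]}),
    )
    effect = QNode(
        "effect",
        ("hi", "lo"),
        ("cause",),
        CondAmplitudeTable(
            {
                ("on",): [math.sqrt(0.9), math.sqrt(0.1)],
                ("off",): [math.sqrt(0.2), math.sqrt(0.8)],
            }
        ),
        basis_rotation=float(rotation),
    )
    return QuantumNetwork([cause, effect])


def random_network(
    rng: np.random.Generator,
    n_nodes: int = 4,
    max_parents: int = 2,
    random_phases: bool = False,
) -> QuantumNetwork:
    """A random binary-node DAG with Dirichlet-uniform table rows.

    Nodes ``n0..n{k-1}`` are ordered; each node draws up to ``max_parents``
    parents from its predecessors.  Row probabilities are kept away from 0
    so that any evidence is conditionable.  With ``random_phases`` each
    table entry gets an independent uniform phase in [0, 2π).
    """
    if n_nodes < 1:
        raise DomainError("need at least one node")
    nodes = []
    names = [f"n{i}" for i in range(n_nodes)]
    for i, name in enumerate(names):
        k = int(rng.integers(0, min(i, max_parents) + 1))
        parents = tuple(
            names[j] for j in sorted(rng.choice(i, size=k, replace=False))
        ) if k else ()
        rows = {}
        import itertools

        for cfg in itertools.product(*(("f", "t"),) * len(parents)):
            p = float(rng.uniform(0.05, 0.95))
            probs = [p, 1.0 - p]
            if random_phases:
                ths = rng.uniform(0.0, 2.0 * math.pi, size=2)
            else:
                ths = (0.0, 0.0)
            rows[cfg] = [
                math.sqrt(q) * complex(math.cos(t), math.sin(t))
                for q, t in zip(probs, ths)
            ]
        nodes.append(QNode(name, ("f", "t"), parents, CondAmplitudeTable(rows)))
    return QuantumNetwork(nodes)


@dataclass
class FixtureSpec:
    """Recipe for emitting a named fixture file deterministically.

    The same name, parameters, and seed always produce byte-identical
    output.  ``seed`` only matters when ``randomize`` is set, which replaces
    the documented placeholder values with seeded draws.
    """

    name: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    randomize: bool = False

    KNOWN = ("bat", "roshambo", "spruce")

    def build(self):
        """Return the in-memory model (QuantumNetwork or TransitionGraph)."""
        if self.name == "bat":
            rng = np.random.default_rng(self.seed) if self.randomize else None
            return bat_network(rng=rng, **self.parameters)
        if self.name == "roshambo":
            return roshambo_network()
        if self.name == "spruce":
            return spruce_graph(**self.parameters)
        raise DomainError(
            f"unknown fixture {self.name!r}; known: {list(self.KNOWN)}"
        )


def emit_fixture(spec: FixtureSpec, path) -> None:
    """Write the fixture to ``path`` in its native dialect (network JSON
    for bat/roshambo, transition-graph JSON/CSV for spruce).

    Emission is deterministic: identical name, parameters, and seed always
    produce byte-identical files.
    """
    from . import io  # deferred: io imports the model modules

    model = spec.build()
    if isinstance(model, TransitionGraph):
        io.write_graph(model, path)
    else:
        io.write_network(model, path)
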