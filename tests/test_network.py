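"""Network structure, enumeration inference, interference, ordered evidence."""

import itertools
import math

import numpy as np
import pytest

from ecoqbn import (
    CondAmplitudeTable,
    OrderedEvidence,
    QNode,
    QuantumNetwork,
    classical_joint,
    information_gain,
    joint_amplitude,
    posterior,
    random_network,
    rotated_pair_network,
    sequential_condition,
    validate_network,
)
from ecoqbn.errors import DomainError, MeasurementError, NetworkError
from ecoqbn.fixtures import BAT_GOOD_GIVEN, BAT_WOODLAND_PRIOR, MOVES


def single_root(p=0.1):
    return QuantumNetwork(
        [QNode("r", ("t", "f"),
               (), CondAmplitudeTable({(): [math.sqrt(p), math.sqrt(1 - p)]}))]
    )


def brute_force_posterior(net, query, evidence, mode):
    """Independent oracle: enumerate every joint assignment, multiply raw
    table entries, and apply the documented coherent-mass definition."""
    names = list(net.nodes)
    states = [net.nodes[n].states for n in names]
    qnode = net.nodes[query]
    bundles = {s: [] for s in qnode.states}
    for combo in itertools.product(*states):
        asg = dict(zip(names, combo))
        if any(asg[n] != s for n, s in evidence.items()):
            continue
        z = 1.0 + 0.0j
        for n in names:
            node = net.nodes[n]
            cfg = tuple(asg[p] for p in node.parents)
            z *= node.table.rows[cfg][node.states.index(asg[n])]
        bundles[asg[query]].append(z)
    masses = {}
    for s, amps in bundles.items():
        classical = sum(abs(z) ** 2 for z in amps)
        if mode == "classical" or not amps:
            masses[s] = classical
        else:
            vis = abs(sum(amps)) ** 2 / sum(abs(z) for z in amps) ** 2
            masses[s] = classical * vis
    total = sum(masses.values())
    return np.array([masses[s] / total for s in qnode.states])


class TestValidation:
    def test_fixtures_are_valid(self, bat, roshambo):
        assert validate_network(bat).ok
        assert validate_network(roshambo).ok

    def test_unnormalized_row_cited(self):
        net = QuantumNetwork(
            [QNode("x", ("a", "b"), (),
                   CondAmplitudeTable({(): [0.9, 0.6]}))]
        )
        report = validate_network(net)
        assert not report.ok
        assert any("sum to 1.17" in i and "()" in i for i in report.issues)

    def test_cycle_redirects_to_transition_graphs(self):
        t = CondAmplitudeTable(
            {("a",): [1.0, 0.0], ("b",): [0.0, 1.0]}
        )
        net = QuantumNetwork(
            [QNode("A", ("a", "b"), ("B",), t),
             QNode("B", ("a", "b"), ("A",), t)]
        )
        report = validate_network(net)
        assert any("TransitionGraph" in i for i in report.issues)
        with pytest.raises(NetworkError, match="acyclic"):
            net.topological_order()

    def test_dangling_parent_and_missing_row(self, bat):
        net = QuantumNetwork(
            [QNode("x", ("a", "b"), ("ghost",), CondAmplitudeTable({}))]
        )
        assert any("ghost" in i for i in validate_network(net).issues)
        habitat = bat.nodes["habitat"]
        broken = CondAmplitudeTable(
            {k: v for k, v in habitat.table.rows.items()
             if k != ("absent", "absent")}
        )
        net2 = QuantumNetwork(
            [bat.nodes["riparian"], bat.nodes["woodland_scrub_savanna"],
             QNode("habitat", habitat.states, habitat.parents, broken)]
        )
        assert any("('absent', 'absent')" in i for i in validate_network(net2).issues)


class TestJoint:
    def test_single_root_prior(self):
        assert classical_joint(single_root(0.1), {"r": "t"}) == pytest.approx(
            0.1, abs=1e-12
        )

    def test_deterministic_chain(self):
        ident = CondAmplitudeTable({("a",): [1.0, 0.0], ("b",): [0.0, 1.0]})
        net = QuantumNetwork(
            [QNode("x", ("a", "b"), (),
                   CondAmplitudeTable({(): [1.0, 0.0]})),
             QNode("y", ("a", "b"), ("x",), ident)]
        )
        assert classical_joint(net, {"x": "a", "y": "a"}) == 1.0
        assert classical_joint(net, {"x": "a", "y": "b"}) == 0.0

    def test_roshambo_joint(self, roshambo):
        p = classical_joint(
            roshambo,
            {"player1": "rock", "player2": "scissors", "outcome": "p1_wins"},
        )
        assert p == pytest.approx(1.0 / 9.0, abs=1e-12)

    def test_joints_sum_to_one(self, bat):
        total = sum(
            classical_joint(bat, dict(zip(bat.nodes, combo)))
            for combo in itertools.product(
                *(n.states for n in bat.nodes.values())
            )
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_amplitude_is_sqrt_of_classical_at_zero_phase(self, bat):
        asg = {"riparian": "present", "woodland_scrub_savanna": "present",
               "habitat": "good"}
        a = joint_amplitude(bat, asg)
        assert a.magnitude == pytest.approx(
            math.sqrt(classical_joint(bat, asg)), abs=1e-12
        )
        assert a.magnitude == pytest.approx(
            0.3162 * math.sqrt(BAT_WOODLAND_PRIOR * 0.9), abs=1e-4
        )

    def test_chain_phases_add(self):
        t1, t2 = 1.1, 2.3
        z = complex(math.cos(t1), math.sin(t1))
        w = complex(math.cos(t2), math.sin(t2))
        net = QuantumNetwork(
            [QNode("x", ("a", "b"), (), CondAmplitudeTable({(): [z, 0.0]})),
             QNode("y", ("a", "b"), ("x",),
                   CondAmplitudeTable({("a",): [w, 0.0], ("b",): [0.0, 1.0]}))]
        )
        a = joint_amplitude(net, {"x": "a", "y": "a"})
        assert a.phase.value == pytest.approx(t1 + t2, abs=1e-9)

    def test_incomplete_assignment_rejected(self, bat):
        with pytest.raises(DomainError, match="missing"):
            classical_joint(bat, {"riparian": "present"})


class TestPosterior:
    def test_bat_evidence_matches_table_row(self, bat):
        post = posterior(
            bat, "habitat",
            [("riparian", "present"), ("woodland_scrub_savanna", "present")],
        )
        expected = BAT_GOOD_GIVEN[("present", "present")]
        assert post["good"] == pytest.approx(expected, abs=1e-12)

    def test_root_prior_without_evidence(self, bat):
        post = posterior(bat, "riparian")
        assert post["present"] == pytest.approx(0.1, abs=1e-12)

    def test_distribution_normalized(self, rng):
        net = random_network(rng, 4, random_phases=True)
        for mode in ("classical", "coherent"):
            post = posterior(net, "n3", [("n0", "t")], mode=mode)
            assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_collider_with_opposed_phases_interferes(self):
        """Two parents feeding a collider with π-separated phases: the
        hidden-parent bundles interfere and shift the coherent posterior."""
        h = 1.0 / math.sqrt(2.0)
        parent = CondAmplitudeTable({(): [h, h]})
        rows = {}
        for a, b in itertools.product("tf", "tf"):
            # child mixes parents; phase π on one parent branch
            sign = -1.0 if a == "t" else 1.0
            rows[(a, b)] = [sign * h, h]
        net = QuantumNetwork(
            [QNode("p1", ("t", "f"), (), parent),
             QNode("p2", ("t", "f"), (), parent),
             QNode("c", ("t", "f"), ("p1", "p2"), CondAmplitudeTable(rows))]
        )
        classical = posterior(net, "c", None, mode="classical")
        coherent = posterior(net, "c", None, mode="coherent")
        assert not np.allclose(
            classical.probabilities, coherent.probabilities, atol=1e-6
        )
        rep = coherent.interference["t"]
        assert rep.coherent_probability == pytest.approx(
            rep.classical_sum + rep.interference_term, abs=1e-12
        )

    def test_zero_probability_evidence_rejected(self):
        net = single_root(1.0)
        child = QNode(
            "y", ("a", "b"), ("r",),
            CondAmplitudeTable({("t",): [1.0, 0.0], ("f",): [0.0, 1.0]}),
        )
        net2 = QuantumNetwork([net.nodes["r"], child])
        with pytest.raises(MeasurementError, match="impossible"):
            posterior(net2, "r", [("y", "b")])

    def test_evidence_on_query_rejected(self, bat):
        with pytest.raises(DomainError):
            posterior(bat, "habitat", [("habitat", "good")])

    def test_rotated_evidence_refused(self):
        net = rotated_pair_network()
        with pytest.raises(DomainError, match="sequential_condition"):
            posterior(net, "cause", [("effect", "hi")])

    @pytest.mark.parametrize("seed", range(30))
    def test_classical_reduction_and_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(2, 5))
        net = random_network(rng, n, random_phases=bool(seed % 2))
        query = f"n{n - 1}"
        evidence = {"n0": "t"} if n > 1 else {}
        for mode in ("classical", "coherent"):
            post = posterior(net, query, list(evidence.items()) or None, mode=mode)
            oracle = brute_force_posterior(net, query, evidence, mode)
            assert np.allclose(post.probabilities, oracle, atol=1e-10)
        if not (seed % 2):  # zero phases: coherent must equal classical
            c = posterior(net, query, list(evidence.items()) or None, "classical")
            q = posterior(net, query, list(evidence.items()) or None, "coherent")
            assert np.allclose(c.probabilities, q.probabilities, atol=1e-12)


class TestOrderedEvidence:
    def test_duplicate_node_rejected(self):
        with pytest.raises(DomainError):
            OrderedEvidence([("a", "x"), ("a", "y")])

    def test_order_preserved_and_reversible(self):
        ev = OrderedEvidence([("a", "x"), ("b", "y")])
        assert [f.node for f in ev] == ["a", "b"]
        assert [f.node for f in ev.reversed()] == ["b", "a"]

    def test_unrotated_orders_agree(self, bat):
        ev = OrderedEvidence(
            [("riparian", "present"), ("woodland_scrub_savanna", "absent")]
        )
        r1 = sequential_condition(bat, ev)
        r2 = sequential_condition(bat, ev.reversed())
        assert r1.regime == "joint"
        assert r1.state.isclose(r2.state, tol=1e-12)

    def test_single_unrotated_finding_matches_posterior(self, bat):
        r = sequential_condition(bat, [("riparian", "present")])
        direct = posterior(bat, "habitat", [("riparian", "present")])
        marg = r.marginal("habitat")
        for s in direct.states:
            assert marg[s] == pytest.approx(direct[s], abs=1e-12)

    def test_rotated_example_is_order_sensitive(self):
        net = rotated_pair_network()
        ev = OrderedEvidence([("cause", "on"), ("effect", "hi")])
        r1 = sequential_condition(net, ev)
        r2 = sequential_condition(net, ev.reversed())
        assert r1.regime == r2.regime == "shared"
        gap = max(
            abs(r1.marginal("cause")[s] - r2.marginal("cause")[s])
            for s in ("on", "off")
        )
        assert gap > 0.01

    def test_rotated_gap_reproducible(self):
        net = rotated_pair_network()
        ev = OrderedEvidence([("cause", "on"), ("effect", "hi")])
        g1 = sequential_condition(net, ev).marginal("cause")["on"]
        g2 = sequential_condition(net, ev).marginal("cause")["on"]
        assert g1 == g2

    def test_impossible_finding_names_step(self):
        net = QuantumNetwork(
            [QNode("x", ("a", "b"), (),
                   CondAmplitudeTable({(): [1.0, 0.0]}))]
        )
        with pytest.raises(MeasurementError, match="finding 1"):
            sequential_condition(net, [("x", "b")])


class TestInformationGain:
    @pytest.mark.parametrize("player", ["player1", "player2"])
    @pytest.mark.parametrize("move", MOVES)
    def test_single_move_gives_no_information(self, roshambo, player, move):
        assert information_gain(roshambo, (player, move), "outcome") == 0.0

    @pytest.mark.parametrize("m1,m2", list(itertools.product(MOVES, MOVES)))
    def test_both_moves_determine_outcome(self, roshambo, m1, m2):
        post = posterior(
            roshambo, "outcome", [("player1", m1), ("player2", m2)]
        )
        assert sorted(post.probabilities) == pytest.approx([0.0, 0.0, 1.0])
        gain = information_gain(
            roshambo, [("player1", m1), ("player2", m2)], "outcome"
        )
        assert gain == pytest.approx(math.log(3.0), abs=1e-12)

    def test_isolated_node_gives_no_information(self, rng):
        net = QuantumNetwork(
            [QNode("iso", ("a", "b"), (),
                   CondAmplitudeTable({(): [math.sqrt(0.4), math.sqrt(0.6)]})),
             QNode("q", ("a", "b"), (),
                   CondAmplitudeTable({(): [math.sqrt(0.3), math.sqrt(0.7)]}))]
        )
        assert information_gain(net, ("iso", "a"), "q") == pytest.approx(
            0.0, abs=1e-15
        )
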