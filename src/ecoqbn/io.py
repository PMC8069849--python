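"""Readers and writers for the network and transition-graph file dialects.

Network dialect (JSON)::

    {"nodes": [{"name": "habitat",
                "states": ["good", "poor"],
                "parents": ["riparian"],
                "cpt": [{"given": {"riparian": "present"},
                         "amps": [{"p": 0.9, "theta": 0.0},
                                  {"p": 0.1}]}],
                "basis_rotation": 0.0}]}

Amplitudes are accepted either as ``{"p": probability, "theta": radians}``
(theta optional, default 0) or as rectangular ``{"re": ..., "im": ...}``;
the polar form is what writers emit.  A classical BN file — no theta keys
anywhere — therefore loads as a valid network whose inference reduces
exactly to classical Bayes.

Transition-graph dialect (JSON)::

    {"states": ["black_spruce", "bog", "shrubland"],
     "edges": [{"from": "black_spruce", "to": "bog",
                "label": "thermokarst", "p": 0.7, "theta": 0.0}]}

plus an equivalent CSV edge list (header ``from,to,label,p,theta``) for
spreadsheet-authored models.  Readers reject unknown keys, naming the
offending path; writers and readers round-trip the in-memory model.
"""

from __future__ import annotations

import cmath
import csv
import json
import math
from pathlib import Path
from typing import Any

from .amplitude import Amplitude, Phase
from .entrainment import PhaseTrajectory
from .errors import ParseError
from .network import CondAmplitudeTable, QNode, QuantumNetwork
from .paths import Edge, TransitionGraph


def _reject_unknown(obj: dict, allowed: set[str], where: str):
    extra = set(obj) - allowed
    if extra:
        raise ParseError(
            f"{where}: unknown key(s) {sorted(extra)}; allowed: {sorted(allowed)}"
        )


def _amp_from_json(obj: Any, where: str) -> complex:
    if not isinstance(obj, dict):
        raise ParseError(f"{where}: amplitude must be an object, got {obj!r}")
    if "re" in obj or "im" in obj:
        _reject_unknown(obj, {"re", "im"}, where)
        return complex(float(obj.get("re", 0.0)), float(obj.get("im", 0.0)))
    _reject_unknown(obj, {"p", "theta"}, where)
    if "p" not in obj:
        raise ParseError(f"{where}: amplitude needs 'p' (or 're'/'im')")
    p = float(obj["p"])
    if not (0.0 <= p <= 1.0):
        raise ParseError(f"{where}: p={p} outside [0, 1]")
    theta = float(obj.get("theta", 0.0))
    return cmath.rect(math.sqrt(p), theta)


def _amp_to_json(z: complex) -> dict:
    a = Amplitude.from_complex(z)
    out: dict[str, float] = {"p": a.magnitude**2}
    if a.phase.value != 0.0:
        out["theta"] = a.phase.value
    return out


def read_network(path: str | Path) -> QuantumNetwork:
    """Parse a network JSON file; malformed input raises :class:`ParseError`
    with the offending key path."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from None
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: top level must be an object")
    _reject_unknown(doc, {"nodes"}, str(path))
    nodes_raw = doc.get("nodes")
    if not isinstance(nodes_raw, list):
        raise ParseError(f"{path}: 'nodes' must be a list")
    nodes = []
    for i, nd in enumerate(nodes_raw):
        where = f"{path}: nodes[{i}]"
        if not isinstance(nd, dict):
            raise ParseError(f"{where}: node must be an object")
        _reject_unknown(
            nd, {"name", "states", "parents", "cpt", "basis_rotation"}, where
        )
        for req in ("name", "states", "cpt"):
            if req not in nd:
                raise ParseError(f"{where}: missing required key {req!r}")
        name = str(nd["name"])
        states = tuple(str(s) for s in nd["states"])
        parents = tuple(str(p) for p in nd.get("parents", ()))
        rows: dict[tuple[str, ...], list[complex]] = {}
        for j, row in enumerate(nd["cpt"]):
            rw = f"{where}.cpt[{j}]"
            if not isinstance(row, dict):
                raise ParseError(f"{rw}: row must be an object")
            _reject_unknown(row, {"given", "amps"}, rw)
            given = row.get("given", {})
            if not isinstance(given, dict):
                raise ParseError(f"{rw}: 'given' must be an object")
            unknown_parents = set(given) - set(parents)
            if unknown_parents:
                raise ParseError(
                    f"{rw}: 'given' names non-parents {sorted(unknown_parents)}"
                )
            missing = set(parents) - set(given)
            if missing:
                raise ParseError(
                    f"{rw}: 'given' missing parent(s) {sorted(missing)}"
                )
            cfg = tuple(str(given[p]) for p in parents)
            if cfg in rows:
                raise ParseError(f"{rw}: duplicate row for configuration {cfg}")
            amps = row.get("amps")
            if not isinstance(amps, list):
                raise ParseError(f"{rw}: 'amps' must be a list")
            rows[cfg] = [
                _amp_from_json(a, f"{rw}.amps[{k}]") for k, a in enumerate(amps)
            ]
        nodes.append(
            QNode(
                name,
                states,
                parents,
                CondAmplitudeTable(rows),
                float(nd.get("basis_rotation", 0.0)),
            )
        )
    return QuantumNetwork(nodes)


def write_network(net: QuantumNetwork, path: str | Path):
    """Emit the network JSON dialect (polar amplitude form)."""
    doc = {"nodes": []}
    for node in net.nodes.values():
        nd: dict[str, Any] = {
            "name": node.name,
            "states": list(node.states),
            "parents": list(node.parents),
            "cpt": [
                {
                    "given": dict(zip(node.parents, cfg)),
                    "amps": [_amp_to_json(z) for z in vec],
                }
                for cfg, vec in sorted(node.table.rows.items())
            ],
        }
        if node.basis_rotation:
            nd["basis_rotation"] = node.basis_rotation
        doc["nodes"].append(nd)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


_EDGE_KEYS = {"from", "to", "label", "p", "theta"}


def _edge_from_mapping(obj: dict, where: str) -> Edge:
    _reject_unknown(obj, _EDGE_KEYS, where)
    for req in ("from", "to", "label", "p"):
        if req not in obj or obj[req] in ("", None):
            raise ParseError(f"{where}: missing required key {req!r}")
    p = float(obj["p"])
    if not (0.0 < p <= 1.0):
        raise ParseError(f"{where}: p={p} outside (0, 1]")
    theta = float(obj.get("theta") or 0.0)
    return Edge(
        str(obj["from"]),
        str(obj["to"]),
        str(obj["label"]),
        Amplitude(math.sqrt(p), Phase(theta)),
    )


def read_graph(path: str | Path) -> TransitionGraph:
    """Parse a transition graph from JSON, or from a CSV edge list when the
    file suffix is ``.csv`` (states inferred from the edges)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_graph_csv(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from None
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: top level must be an object")
    _reject_unknown(doc, {"states", "edges"}, str(path))
    states = doc.get("states")
    edges_raw = doc.get("edges")
    if not isinstance(states, list) or not isinstance(edges_raw, list):
        raise ParseError(f"{path}: 'states' and 'edges' must be lists")
    edges = [
        _edge_from_mapping(e, f"{path}: edges[{i}]")
        for i, e in enumerate(edges_raw)
    ]
    return TransitionGraph([str(s) for s in states], edges)


def _read_graph_csv(path: Path) -> TransitionGraph:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) - _EDGE_KEYS:
            raise ParseError(
                f"{path}: CSV header must be from,to,label,p[,theta]; "
                f"got {reader.fieldnames}"
            )
        edges = [
            _edge_from_mapping(
                {k: v for k, v in row.items() if v not in (None, "")},
                f"{path}: line {i}",
            )
            for i, row in enumerate(reader, start=2)
        ]
    states: list[str] = []
    for e in edges:
        for s in (e.source, e.target):
            if s not in states:
                states.append(s)
    return TransitionGraph(states, edges)


def write_graph(g: TransitionGraph, path: str | Path):
    """Emit graph JSON, or a CSV edge list when the suffix is ``.csv``."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["from", "to", "label", "p", "theta"])
            for e in g.edges:
                w.writerow(
                    [e.source, e.target, e.label, repr(e.probability),
                     repr(e.amplitude.phase.value)]
                )
        return
    doc = {
        "states": list(g.states),
        "edges": [
            {
                "from": e.source,
                "to": e.target,
                "label": e.label,
                "p": e.probability,
                "theta": e.amplitude.phase.value,
            }
            for e in g.edges
        ],
    }
    path.write_text(json.dumps(doc, indent=2) + "\n")


def write_trajectory(traj: PhaseTrajectory, path: str | Path):
    """CSV dump of a phase trajectory: time, theta1, theta2, delta."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "theta1", "theta2", "delta"])
        for t, a, b in zip(traj.times, traj.theta1, traj.theta2):
            w.writerow([repr(float(t)), repr(float(a)), repr(float(b)),
                        repr(float(a - b))])
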