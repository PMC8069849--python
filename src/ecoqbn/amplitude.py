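"""Complex probability amplitudes, state vectors, and Born-rule measurement.

A probability amplitude is a complex number ``sqrt(p) * exp(i*theta)`` whose
squared magnitude is a classical probability ``p``.  A system over a finite,
labelled basis is described by a unit-norm vector of amplitudes (the wave
function); measuring the system projects that vector onto the subspace of the
observed outcome and renormalizes it (collapse).  The probability of the
outcome is the squared norm of the projection (Born's rule).

The module reduces exactly to classical probability when every phase is zero:
amplitudes become nonnegative square roots and Born probabilities become the
underlying classical masses.  Interference — the departure of a coherent sum
``|Σψ|²`` from the classical sum ``Σ|ψ|²`` — is exposed explicitly through
:func:`interfere` and :class:`InterferenceReport`.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    BasisError,
    DomainError,
    MeasurementError,
    NormalizationError,
    ShapeError,
)

TWO_PI = 2.0 * math.pi

#: Tolerance for unit-norm checks on state vectors and table rows.
NORM_TOL = 1e-9
#: Tolerance for modular phase equality.
PHASE_TOL = 1e-9
#: Probabilities below this are treated as impossible events in collapse.
ZERO_PROB = 1e-12


@dataclass(frozen=True)
class Phase:
    """An angle in radians, canonicalized into ``[0, 2π)``.

    Two phases that differ by an exact multiple of 2π compare equal.
    """

    value: float

    def __post_init__(self):
        v = float(self.value)
        if not math.isfinite(v):
            raise DomainError(f"phase must be finite, got {v!r}")
        v = math.fmod(v, TWO_PI)
        if v < 0.0:
            v += TWO_PI
        # fmod can return TWO_PI itself after the negative correction when
        # v was a tiny negative number; fold that back to 0.
        if v >= TWO_PI:
            v -= TWO_PI
        object.__setattr__(self, "value", v)

    def __eq__(self, other):
        if isinstance(other, Phase):
            other = other.value
        elif not isinstance(other, (int, float)):
            return NotImplemented
        d = math.fmod(self.value - float(other), TWO_PI)
        if d < 0:
            d += TWO_PI
        return d < PHASE_TOL or TWO_PI - d < PHASE_TOL

    def __hash__(self):
        # Equality is tolerance-based; hash only on the canonical bucket 0 to
        # keep the (rarely used) hash contract safe.
        return hash(Phase)

    def __add__(self, other: "Phase | float") -> "Phase":
        o = other.value if isinstance(other, Phase) else float(other)
        return Phase(self.value + o)

    def __sub__(self, other: "Phase | float") -> "Phase":
        o = other.value if isinstance(other, Phase) else float(other)
        return Phase(self.value - o)


@dataclass(frozen=True)
class Amplitude:
    """A probability amplitude ``magnitude * exp(i * phase)``.

    ``magnitude`` lies in [0, 1] so that the squared magnitude is a valid
    classical probability.
    """

    magnitude: float
    phase: Phase = field(default_factory=lambda: Phase(0.0))

    def __post_init__(self):
        m = float(self.magnitude)
        if not (0.0 <= m <= 1.0 + 1e-12):
            raise DomainError(f"amplitude magnitude must be in [0, 1], got {m!r}")
        object.__setattr__(self, "magnitude", min(m, 1.0))
        if not isinstance(self.phase, Phase):
            object.__setattr__(self, "phase", Phase(float(self.phase)))

    @classmethod
    def from_complex(cls, z: complex) -> "Amplitude":
        return cls(abs(z), Phase(cmath.phase(z)))

    def to_complex(self) -> complex:
        return cmath.rect(self.magnitude, self.phase.value)


def amplitude_from_probability(p: float, theta: Phase | float = 0.0) -> Amplitude:
    """Convert a classical probability to the amplitude ``sqrt(p)·e^{iθ}``.

    The squared magnitude of the result reproduces ``p`` exactly to within
    1e-12, e.g. p = 0.1 gives magnitude 0.3162 (4 d.p.).
    """
    p = float(p)
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"probability must lie in [0, 1], got {p!r}")
    theta = theta if isinstance(theta, Phase) else Phase(float(theta))
    return Amplitude(math.sqrt(p), theta)


def to_probability(a: Amplitude) -> float:
    """Squared magnitude of an amplitude: the classical probability.

    Independent of the phase: ``|e^{iθ}/√2|² = 0.5`` for every θ.
    """
    return a.magnitude * a.magnitude


@dataclass(frozen=True)
class StateLabel:
    """A named basis state with its position in the basis ordering."""

    name: str
    ordinal: int


class Basis:
    """An ordered set of uniquely named basis states."""

    def __init__(self, names: Sequence[str]):
        names = [str(n) for n in names]
        if len(set(names)) != len(names):
            raise DomainError(f"basis labels must be unique, got {names}")
        if not names:
            raise DomainError("basis must contain at least one state")
        self.labels: tuple[StateLabel, ...] = tuple(
            StateLabel(n, i) for i, n in enumerate(names)
        )
        self._index = {n: i for i, n in enumerate(names)}

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.labels)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise BasisError(f"state {name!r} not in basis {self.names}") from None

    def __len__(self):
        return len(self.labels)

    def __eq__(self, other):
        return isinstance(other, Basis) and self.names == other.names

    def __hash__(self):
        return hash(self.names)

    def __repr__(self):
        return f"Basis({list(self.names)!r})"


class StateVector:
    """A unit-norm vector of amplitudes over a labelled basis (the wave
    function ψ).

    Construction rejects vectors whose L2 norm deviates from 1 by more than
    ``NORM_TOL`` rather than silently renormalizing — call
    :meth:`renormalized` explicitly when that is intended.  The squared
    magnitudes of a valid state vector form a classical distribution.
    """

    def __init__(self, basis: Basis, amplitudes: Iterable[complex | Amplitude]):
        amps = [
            a.to_complex() if isinstance(a, Amplitude) else complex(a)
            for a in amplitudes
        ]
        if len(amps) != len(basis):
            raise ShapeError(
                f"{len(amps)} amplitudes for a basis of {len(basis)} states"
            )
        vec = np.asarray(amps, dtype=complex)
        nrm = float(np.linalg.norm(vec))
        if abs(nrm - 1.0) > NORM_TOL:
            raise NormalizationError(
                f"state vector norm is {nrm!r}, not 1 (tolerance {NORM_TOL}); "
                "call StateVector.renormalized to normalize explicitly"
            )
        self.basis = basis
        self.vector = vec

    @classmethod
    def renormalized(
        cls, basis: Basis, amplitudes: Iterable[complex | Amplitude]
    ) -> "StateVector":
        """Build a state vector, explicitly rescaling to unit norm."""
        amps = np.asarray(
            [
                a.to_complex() if isinstance(a, Amplitude) else complex(a)
                for a in amplitudes
            ],
            dtype=complex,
        )
        nrm = float(np.linalg.norm(amps))
        if nrm <= 0.0:
            raise NormalizationError("cannot normalize the zero vector")
        return cls(basis, amps / nrm)

    @property
    def amplitudes(self) -> tuple[Amplitude, ...]:
        return tuple(Amplitude.from_complex(z) for z in self.vector)

    def probabilities(self) -> np.ndarray:
        """Squared magnitudes: the classical distribution over the basis."""
        return np.abs(self.vector) ** 2

    def isclose(self, other: "StateVector", tol: float = 1e-12) -> bool:
        return self.basis == other.basis and bool(
            np.allclose(self.vector, other.vector, atol=tol, rtol=0.0)
        )

    def __repr__(self):
        pairs = ", ".join(
            f"{n}: {z:.4f}" for n, z in zip(self.basis.names, self.vector)
        )
        return f"StateVector({pairs})"


def superpose(
    probs: Sequence[float],
    phases: Sequence[Phase | float] | None,
    basis: Basis | None = None,
) -> StateVector:
    """Build the superposition ``Σ √p_i · e^{iθ_i} |i⟩`` from a classical
    distribution and one phase per state.

    ``probs`` must sum to 1 within 1e-9.  With ``phases=None`` all phases are
    zero and the result is the classical square-root embedding.
    """
    probs = [float(p) for p in probs]
    if phases is None:
        phases = [0.0] * len(probs)
    if len(phases) != len(probs):
        raise ShapeError(
            f"{len(probs)} probabilities but {len(phases)} phases"
        )
    total = sum(probs)
    if abs(total - 1.0) > NORM_TOL:
        raise NormalizationError(f"probabilities sum to {total!r}, not 1")
    if basis is None:
        basis = Basis([f"s{i}" for i in range(len(probs))])
    amps = [amplitude_from_probability(p, th) for p, th in zip(probs, phases)]
    # Rounding in sqrt can leave the norm a hair off 1; rescale within NORM_TOL.
    return StateVector.renormalized(basis, amps)


class Projector:
    """Projection onto the subspace spanned by a subset of basis states.

    Idempotent by construction: applying it twice equals applying it once,
    element-wise exactly (entries are kept or zeroed).
    """

    def __init__(self, basis: Basis, kept: Iterable[int | str]):
        idx = sorted(
            {basis.index(k) if isinstance(k, str) else int(k) for k in kept}
        )
        if not idx:
            raise DomainError("projector must keep at least one basis state")
        if idx[0] < 0 or idx[-1] >= len(basis):
            raise BasisError(
                f"projector indices {idx} out of range for basis of {len(basis)}"
            )
        self.basis = basis
        self.kept: tuple[int, ...] = tuple(idx)
        self._mask = np.zeros(len(basis))
        self._mask[list(idx)] = 1.0

    @classmethod
    def onto(cls, basis: Basis, *names: str) -> "Projector":
        return cls(basis, names)

    def apply(self, vector: np.ndarray) -> np.ndarray:
        return vector * self._mask

    def is_disjoint(self, other: "Projector") -> bool:
        return not set(self.kept) & set(other.kept)

    def __repr__(self):
        names = [self.basis.names[i] for i in self.kept]
        return f"Projector(onto {names})"


class Observable:
    """A Hermitian operator ``Σ λ_i P_i``: real eigenvalues attached to
    mutually disjoint projectors that jointly cover the basis.

    Eigenvalues default to the state ordinals of each projector's first kept
    state.
    """

    def __init__(self, eigenpairs: Sequence[tuple[float, Projector]]):
        if not eigenpairs:
            raise DomainError("observable needs at least one eigenpair")
        basis = eigenpairs[0][1].basis
        covered: set[int] = set()
        for _, proj in eigenpairs:
            if proj.basis != basis:
                raise BasisError("all projectors must share one basis")
            if covered & set(proj.kept):
                raise DomainError("observable projectors must be disjoint")
            covered |= set(proj.kept)
        if covered != set(range(len(basis))):
            raise DomainError("observable projectors must cover the basis")
        self.basis = basis
        self.eigenpairs: tuple[tuple[float, Projector], ...] = tuple(
            (float(v), p) for v, p in eigenpairs
        )

    @classmethod
    def diagonal(cls, basis: Basis) -> "Observable":
        """One projector per basis state, eigenvalue = state ordinal."""
        return cls([(i, Projector(basis, [i])) for i in range(len(basis))])

    def expectation(self, psi: StateVector) -> float:
        return sum(
            v * born_probability(psi, p) for v, p in self.eigenpairs
        )


def born_probability(psi: StateVector, proj: Projector) -> float:
    """Born's rule: ``P = ‖P ψ‖²``, the squared norm of the projected
    state vector.

    Summing over the projectors of any observable gives 1 (the quantum
    analogue of the law of total probability).
    """
    if proj.basis != psi.basis:
        raise BasisError(
            f"projector basis {proj.basis.names} does not match state basis "
            f"{psi.basis.names}"
        )
    return float(np.sum(np.abs(proj.apply(psi.vector)) ** 2))


def collapse(psi: StateVector, proj: Projector) -> StateVector:
    """Project ψ onto an observed subspace and renormalize to unit length
    (collapse of the wave function).

    Amplitudes outside the projector become zero; relative phases inside it
    are preserved exactly.  Conditioning on an event of (near-)zero
    probability raises :class:`MeasurementError`.
    """
    p = born_probability(psi, proj)
    if p <= ZERO_PROB:
        raise MeasurementError(
            f"cannot collapse onto an event of probability {p!r} "
            f"({proj!r}): conditioning on an impossible event"
        )
    projected = proj.apply(psi.vector)
    return StateVector(psi.basis, projected / math.sqrt(p))


def quantum_conditional(
    psi: StateVector, given: Projector, then: Projector
) -> float:
    """Quantum conditional probability ``P(then | given)``.

    Collapse ψ onto ``given``, then measure ``then`` by Born's rule.  With
    all phases equal this reproduces the classical conditional computed from
    the squared magnitudes.
    """
    return born_probability(collapse(psi, given), then)


@dataclass(frozen=True)
class InterferenceReport:
    """Decomposition of a coherent probability into its classical part and
    the interference cross term.

    ``coherent_probability = classical_sum + interference_term`` holds to
    1e-12 by construction.  The coherent value may exceed 1 before any
    normalization — that excess is the signature of constructive
    interference.
    """

    classical_sum: float
    coherent_probability: float
    interference_term: float


def interfere(amplitudes: Sequence[Amplitude | complex]) -> InterferenceReport:
    """Coherently add amplitudes and report the interference decomposition.

    classical_sum   = Σ |ψ_i|²
    coherent        = |Σ ψ_i|²
    interference    = 2 Σ_{i<j} |ψ_i||ψ_j| cos(θ_i − θ_j)

    Equal phases give maximal constructive interference; phases π apart
    cancel.  A single amplitude has no cross term.
    """
    if len(amplitudes) == 0:
        raise DomainError("interfere requires at least one amplitude")
    zs = np.asarray(
        [
            a.to_complex() if isinstance(a, Amplitude) else complex(a)
            for a in amplitudes
        ],
        dtype=complex,
    )
    classical = float(np.sum(np.abs(zs) ** 2))
    coherent = float(abs(np.sum(zs)) ** 2)
    return InterferenceReport(classical, coherent, coherent - classical)


def coherence_visibility(amplitudes: Sequence[Amplitude | complex]) -> float:
    """Visibility ``|Σψ|² / (Σ|ψ|)²`` of an amplitude bundle, in [0, 1].

    1 when all phases are aligned (or for a single amplitude), 0 under
    perfect destructive cancellation.  Used by network inference to modulate
    classical masses by hidden-path interference so that phase-free models
    reduce exactly to classical probability.
    """
    zs = np.asarray(
        [
            a.to_complex() if isinstance(a, Amplitude) else complex(a)
            for a in amplitudes
        ],
        dtype=complex,
    )
    mags = np.abs(zs)
    denom = float(np.sum(mags)) ** 2
    if denom <= 0.0:
        return 1.0
    v = float(abs(np.sum(zs)) ** 2) / denom
    return min(max(v, 0.0), 1.0)
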