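"""Two coupled phase oscillators for signal entrainment and synchrony.

Birdsong duets, cricket choruses, and firefly flashes are modelled as a
pair of phase oscillators with sinusoidal coupling:

    dθ1/dt = w1 + A2·sin(θ2 − θ1)
    dθ2/dt = w2 + A1·sin(θ1 − θ2)

where w1, w2 are the natural signalling frequencies (rad per unit time) and
A1, A2 ≥ 0 the coupling strengths — note the cross-indexing: A2 measures
how strongly oscillator 2 pulls on oscillator 1.

The phase difference Δ = θ1 − θ2 obeys dΔ/dt = (w1−w2) − (A1+A2)·sin Δ, so
a stable locked difference Δ* = arcsin((w1−w2)/(A1+A2)) exists exactly when
|w1−w2| ≤ A1+A2; beyond that the difference drifts without bound.

Two vocabularies are reported side by side and deliberately kept apart:
the *parameter* conditions (entrainment ⇔ A1 = A2; synchrony ⇔ w1 = w2)
and the *empirical* verdict (the trajectory's phase difference settles to a
constant — phase locking).  They disagree in general: unequal couplings can
still lock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError, DomainError


@dataclass(frozen=True)
class OscillatorPair:
    """Parameters of the two coupled oscillators.

    w1, w2     natural frequencies, radians per unit time
    A1, A2     coupling amplitudes, radians per unit time, ≥ 0
    theta1_0, theta2_0   initial phases, radians
    """

    w1: float
    w2: float
    A1: float
    A2: float
    theta1_0: float = 0.0
    theta2_0: float = 0.0

    def __post_init__(self):
        vals = (self.w1, self.w2, self.A1, self.A2, self.theta1_0, self.theta2_0)
        if not all(math.isfinite(v) for v in vals):
            raise DomainError(f"all oscillator parameters must be finite: {vals}")
        if self.A1 < 0 or self.A2 < 0:
            raise DomainError(
                f"coupling amplitudes must be >= 0, got A1={self.A1}, A2={self.A2}"
            )

    @property
    def coupling_sum(self) -> float:
        return self.A1 + self.A2

    @property
    def detuning(self) -> float:
        return self.w1 - self.w2

    def locked_delta_analytic(self) -> float | None:
        """Stable fixed point of the phase difference, or None if the
        detuning exceeds the total coupling (no lock exists)."""
        if self.coupling_sum <= 0.0:
            return 0.0 if self.detuning == 0.0 else None
        r = self.detuning / self.coupling_sum
        if abs(r) > 1.0:
            return None
        return math.asin(r)


@dataclass
class PhaseTrajectory:
    """Sampled solution: strictly increasing times and unwrapped phases."""

    times: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.theta1 = np.asarray(self.theta1, dtype=float)
        self.theta2 = np.asarray(self.theta2, dtype=float)
        if not (len(self.times) == len(self.theta1) == len(self.theta2)):
            raise DataError("trajectory arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("trajectory times must be strictly increasing")

    @property
    def delta(self) -> np.ndarray:
        """Unwrapped phase difference θ1 − θ2."""
        return self.theta1 - self.theta2

    def __len__(self):
        return len(self.times)


def integrate(pair: OscillatorPair, t_end: float, dt: float = 0.01) -> PhaseTrajectory:
    """Integrate the coupled system with fixed-step 4th-order Runge–Kutta.

    Fixed stepping (rather than adaptive) keeps runs bit-reproducible; the
    system is smooth and non-stiff, so RK4 at the default dt = 0.01 is far
    inside its stability region for ecologically plausible parameters.
    Phases are returned unwrapped (no mod-2π folding).
    """
    if dt <= 0 or t_end <= 0:
        raise DomainError(f"dt and t_end must be positive, got dt={dt}, t_end={t_end}")
    if dt > t_end:
        raise DomainError(f"dt={dt} exceeds t_end={t_end}")
    n = int(round(t_end / dt))
    times = np.arange(n + 1) * dt
    th1 = np.empty(n + 1)
    th2 = np.empty(n + 1)
    th1[0], th2[0] = pair.theta1_0, pair.theta2_0
    w1, w2, a1, a2 = pair.w1, pair.w2, pair.A1, pair.A2

    def f(x1: float, x2: float) -> tuple[float, float]:
        s = math.sin(x2 - x1)
        return w1 + a2 * s, w2 - a1 * s

    x1, x2 = th1[0], th2[0]
    for i in range(n):
        k1a, k1b = f(x1, x2)
        k2a, k2b = f(x1 + 0.5 * dt * k1a, x2 + 0.5 * dt * k1b)
        k3a, k3b = f(x1 + 0.5 * dt * k2a, x2 + 0.5 * dt * k2b)
        k4a, k4b = f(x1 + dt * k3a, x2 + dt * k3b)
        x1 += dt * (k1a + 2 * k2a + 2 * k3a + k4a) / 6.0
        x2 += dt * (k1b + 2 * k2b + 2 * k3b + k4b) / 6.0
        th1[i + 1], th2[i + 1] = x1, x2
    return PhaseTrajectory(times, th1, th2)


@dataclass
class EntrainmentVerdict:
    """Side-by-side report of the parameter conditions and the empirical
    phase-locking test.

    ``paper_entrained``/``paper_synchronous`` restate the parameter
    definitions (equal couplings / equal frequencies); ``phase_locked`` is
    measured from the trajectory tail.  ``locked_delta`` (radians, in
    (−π, π]) is present iff the trajectory locked.
    """

    paper_entrained: bool
    paper_synchronous: bool
    phase_locked: bool
    locked_delta: float | None = None

    def __post_init__(self):
        if self.phase_locked != (self.locked_delta is not None):
            raise DataError("locked_delta must be present iff phase_locked")


def _circular_mean(angles: np.ndarray) -> float:
    z = np.exp(1j * angles).mean()
    return float(np.angle(z))


def assess(
    trajectory: PhaseTrajectory,
    pair: OscillatorPair,
    tol: float = 1e-3,
    window: float = 1.0 / 3.0,
) -> EntrainmentVerdict:
    """Judge entrainment/synchrony conditions and empirical phase locking.

    The trajectory is phase-locked when the unwrapped phase difference over
    the final ``window`` fraction (default: last third) varies by less than
    ``tol`` radians; the locked value is the circular mean of that segment,
    reported in (−π, π].
    """
    if tol <= 0:
        raise DomainError(f"tol must be positive, got {tol}")
    if not (0.0 < window <= 1.0):
        raise DomainError(f"window fraction must be in (0, 1], got {window}")
    if len(trajectory) < 10:
        raise DataError(
            f"trajectory has {len(trajectory)} samples; at least 10 required"
        )
    entrained = abs(pair.A1 - pair.A2) <= tol
    synchronous = abs(pair.w1 - pair.w2) <= tol
    tail = trajectory.delta[int(len(trajectory) * (1.0 - window)):]
    locked = bool(np.ptp(tail) < tol)
    locked_delta = _circular_mean(tail) if locked else None
    return EntrainmentVerdict(entrained, synchronous, locked, locked_delta)


def signal_train(
    trajectory: PhaseTrajectory, emit_phase: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Event times at which each oscillator's phase crosses ``emit_phase``
    (mod 2π), located by linear interpolation between samples.

    The two event arrays are the synthetic analogue of call/chirp rasters:
    a synchronized pair's inter-train offsets shrink to zero, an entrained
    duet keeps a constant nonzero offset.
    """
    events = []
    for theta in (trajectory.theta1, trajectory.theta2):
        # index of the 2π-branch each sample sits on
        k = np.floor((theta - emit_phase) / (2.0 * math.pi))
        ts: list[float] = []
        for i in range(len(theta) - 1):
            lo, hi = k[i], k[i + 1]
            if lo == hi:
                continue
            step = 1 if hi > lo else -1
            for branch in np.arange(lo, hi, step):
                target = emit_phase + 2.0 * math.pi * (branch + (1 if step > 0 else 0))
                th0, th1 = theta[i], theta[i + 1]
                if th1 == th0:
                    continue
                frac = (target - th0) / (th1 - th0)
                if 0.0 <= frac <= 1.0:
                    t0, t1 = trajectory.times[i], trajectory.times[i + 1]
                    ts.append(float(t0 + frac * (t1 - t0)))
        events.append(np.asarray(sorted(ts)))
    return events[0], events[1]


def locking_condition(pair: OscillatorPair) -> bool:
    """Analytic condition for a locked phase difference to exist:
    |w1 − w2| ≤ A1 + A2."""
    return abs(pair.detuning) <= pair.coupling_sum
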