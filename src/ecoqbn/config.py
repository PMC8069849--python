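"""Run-time configuration shared by the CLI and long-running scripts."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import DomainError


@dataclass
class RunConfig:
    """Tunable tolerances and caps with their engine-wide defaults.

    norm_tol          unit-norm tolerance for vectors and table rows
    locking_tol       phase-range threshold (radians) for the locking test
    max_joint_states  exact-enumeration cap (2**20 ≈ 20 binary nodes)
    max_path_len      default bound for path/circuit enumeration
    dt                default oscillator integration step (time units)
    out_dir           where CLI subcommands write files
    log_level         standard logging level name
    """

    norm_tol: float = 1e-9
    locking_tol: float = 1e-3
    max_joint_states: int = 2**20
    max_path_len: int = 10
    dt: float = 0.01
    out_dir: Path = field(default_factory=lambda: Path("."))
    log_level: str = "WARNING"

    def __post_init__(self):
        for name in ("norm_tol", "locking_tol", "dt"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        for name in ("max_joint_states", "max_path_len"):
            if getattr(self, name) < 1:
                raise DomainError(f"{name} must be at least 1")
        self.out_dir = Path(self.out_dir)
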