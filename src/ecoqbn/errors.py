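"""Exception hierarchy for the ecoqbn engine.

All engine errors derive from :class:`EcoQBNError`, so callers (including the
CLI) can distinguish data problems (exit code 1) from usage problems (exit
code 2, raised by the argument parser itself).
"""


class EcoQBNError(Exception):
    """Base class for every error raised by the engine."""


class DomainError(EcoQBNError, ValueError):
    """An input value lies outside its mathematical domain."""


class ShapeError(EcoQBNError, ValueError):
    """Mismatched lengths or dimensions between related arguments."""


class BasisError(EcoQBNError, ValueError):
    """An operator and a state vector are defined on different bases."""


class MeasurementError(EcoQBNError, ValueError):
    """Conditioning or collapsing on an event of zero probability."""


class NormalizationError(EcoQBNError, ValueError):
    """A vector or table row violates unit-norm requirements."""


class NetworkError(EcoQBNError, ValueError):
    """A structural problem in a quantum network definition."""


class PathError(EcoQBNError, ValueError):
    """A path does not form a connected chain in its graph."""


class GraphError(EcoQBNError, ValueError):
    """Unknown states, labels, or malformed transition-graph structure."""


class StrandedSequenceError(EcoQBNError, ValueError):
    """A disturbance sequence reached a point where no edge applies.

    Carries the prefix of the sequence that *was* applicable and the state
    distribution reached at that point.
    """

    def __init__(self, message, prefix, distribution):
        super().__init__(message)
        self.prefix = list(prefix)
        self.distribution = dict(distribution)


class DataError(EcoQBNError, ValueError):
    """A trajectory or data container is unusable (e.g., too short)."""


class ParseError(EcoQBNError, ValueError):
    """A network or graph file could not be parsed; message carries context."""
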