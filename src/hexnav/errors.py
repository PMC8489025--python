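"""Exception hierarchy for hexnav."""


class HexNavError(Exception):
    """Base class for all package-specific errors."""


class MazeConfigurationError(HexNavError):
    """Raised when a maze cannot be built as requested (e.g. barriers disconnect it)."""


class DegenerateTrialError(HexNavError):
    """Raised for trials whose metrics are undefined (start == goal, incomplete trial)."""


class ParameterError(HexNavError, ValueError):
    """Raised for out-of-range model or algorithm parameters."""


class FitError(HexNavError):
    """Raised when an optimisation fails to produce a usable fit."""


class GenerationError(HexNavError):
    """Raised when synthetic-protocol generation cannot satisfy its constraints."""


class TrajectoryFormatError(HexNavError):
    """Raised for malformed trajectory files (bad rows, unknown nodes, non-adjacent steps)."""
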