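"""Exception types shared across the package."""


class DirconnError(Exception):
    """Base class for package-specific failures."""


class ParseError(DirconnError, ValueError):
    """A delimited-text file could not be parsed (names the offending cell)."""


class FormatError(DirconnError, ValueError):
    """A file violates the expected layout (e.g. ragged rows)."""


class InvalidParameterError(DirconnError, ValueError):
    """A numeric argument is outside its admissible range."""


class LengthError(DirconnError, ValueError):
    """Not enough samples for the requested segmentation or lag depth."""


class RankError(DirconnError, ValueError):
    """A normal-equation system is numerically singular."""


class ConditioningError(DirconnError, RuntimeError):
    """A frequency-domain matrix is numerically singular."""


class StabilityError(DirconnError, RuntimeError):
    """A dynamical model is unstable (spectral radius / eigenvalue check)."""


class FixedPointError(DirconnError, RuntimeError):
    """Fixed-point search failed to converge."""
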