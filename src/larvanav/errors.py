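"""Exception types shared across the package."""


class LarvanavError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LarvanavError):
    """A file or array does not conform to the expected layout."""


class ValidationError(LarvanavError, ValueError):
    """Input violates a documented invariant (non-monotone times, bad geometry, ...)."""


class InsufficientDataError(LarvanavError):
    """Too few observations to compute the requested quantity."""


class ClassificationError(LarvanavError):
    """The significance pattern is incomplete and cannot be classified."""


class SimulationError(LarvanavError):
    """A forager replicate could not take a feasible step."""
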