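"""Package-level exception types."""


class SkiposeError(Exception):
    """Base class for all skipose errors."""


class FormatError(SkiposeError, ValueError):
    """A file does not conform to the documented dialect (missing columns, ...)."""


class DataError(SkiposeError, ValueError):
    """Data violate an invariant (too few rows, non-monotone time, NaNs, ...)."""


class RangeError(SkiposeError, ValueError):
    """A query point lies outside the supported domain (e.g. mesh bounds)."""


class SyncError(SkiposeError, RuntimeError):
    """Time synchronization could not find the squat landmark."""


class NoSolutionError(SkiposeError, ArithmeticError):
    """The balance equation has no real solution for the given inputs."""


class GenerationError(SkiposeError, RuntimeError):
    """The synthetic-run generator could not satisfy the balance constraint."""
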