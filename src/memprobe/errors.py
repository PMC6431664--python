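"""Exception hierarchy shared across the package.

Errors are deliberately specific so that callers (and the CLI) can
distinguish a bad instrument signal from a malformed input table or a
degenerate model configuration.
"""


class MemprobeError(Exception):
    """Base class for all package errors."""


class InputValidationError(MemprobeError, ValueError):
    """Non-finite, missing, or out-of-range raw input."""


class DegenerateSignalError(MemprobeError, ValueError):
    """Signal combination for which a ratio observable is undefined
    (e.g. I440 + I490 <= 0, or a vanishing anisotropy denominator)."""


class NoTransitionError(MemprobeError, ValueError):
    """A melting-curve fit was requested on data with no discernible
    gel-to-fluid transition."""


class SchemaError(MemprobeError, ValueError):
    """Malformed tabular input: missing columns, duplicate keys with
    incompatible metadata, unknown channel labels."""


class CompositionError(MemprobeError, ValueError):
    """Impossible simulated-system composition (non-integral molecule
    counts, odd leaflet split)."""


class MissingDataError(MemprobeError, ValueError):
    """A required data window (e.g. an injection interval of a power
    trace) contains no samples."""


class FitNonConvergenceError(MemprobeError, RuntimeError):
    """Raised only when a caller asks for strict fitting; the default
    path returns a flagged result instead."""
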