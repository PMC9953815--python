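"""Exception hierarchy.

All domain errors derive from :class:`CoaT2FcmError` so callers (and the
CLI) can catch one base class.  Argument-contract violations additionally
derive from :class:`ValueError`.
"""


class CoaT2FcmError(Exception):
    """Base class for all errors raised by this package."""


class InvalidArgumentError(CoaT2FcmError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(CoaT2FcmError, ValueError):
    """Input is structurally valid but degenerate (e.g. zero variance)."""


class DegenerateClusterError(CoaT2FcmError):
    """A cluster has lost all membership mass."""


class UndefinedMetricError(CoaT2FcmError, ZeroDivisionError):
    """A metric's denominator is zero; refusing to return a sentinel."""


class UnsupportedFormatError(CoaT2FcmError, ValueError):
    """An image file is not a grayscale PGM/PNG this package handles."""


class ConfigError(CoaT2FcmError, ValueError):
    """A run configuration failed validation."""
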