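"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes (validation -> 2, I/O -> 3,
empty result -> 4); library callers catch them directly.
"""


class EcogMapError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EcogMapError):
    """Input data violates a precondition (shape, labels, consistency)."""


class InvalidParameterError(EcogMapError):
    """A parameter is outside its legal range (e.g. band edge >= Nyquist)."""


class InvalidConfigurationError(EcogMapError):
    """A configuration is internally inconsistent or physically impossible."""


class EmptyResultError(EcogMapError):
    """An operation produced no usable output (e.g. all trials rejected)."""


class DegenerateInputError(EcogMapError):
    """Zero-variance or zero-power input where a ratio statistic is undefined."""


class UndefinedMetricError(EcogMapError):
    """A metric's denominator is empty (e.g. no ground-truth positives)."""


class FixtureIOError(EcogMapError):
    """File read/write failure, annotated with the offending path."""
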