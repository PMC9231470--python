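"""Exception hierarchy shared across the package."""


class PyrotraceError(Exception):
    """Base class for all package-specific errors."""


class InputError(PyrotraceError, ValueError):
    """Invalid argument combination or malformed tabular input."""


class DomainError(PyrotraceError, ValueError):
    """A physical quantity lies outside its supported domain."""


class SpectrumParseError(PyrotraceError):
    """A spectrum file could not be parsed; message names the offending line."""


class SpectrumDataError(PyrotraceError):
    """Parsed spectrum data violates an invariant (non-monotone axis, NaN)."""


class TrainingError(PyrotraceError):
    """Model training failed (degenerate target, NaN loss)."""


class UndefinedStatisticError(PyrotraceError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
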