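"""Exception hierarchy shared across the pipeline.

Every anticipated failure mode maps to a distinct class so callers (and the
CLI) can distinguish bad input files from bad configuration from degenerate
data, instead of pattern-matching message strings.
"""


class MMPVError(Exception):
    """Base class for all package errors."""


class ParseError(MMPVError):
    """A file could not be parsed; message carries row/column coordinates."""


class ValidationError(MMPVError):
    """Parsed content violates a contract (bad status string, bad sign...)."""


class DuplicateIdError(ValidationError):
    """Duplicate identifier where uniqueness is required."""


class ConfigurationError(MMPVError):
    """A run was configured inconsistently (unknown feature, bad threshold)."""


class MissingDependencyError(ConfigurationError):
    """A pipeline stage was requested before the stage it depends on."""


class InsufficientDataError(MMPVError):
    """Too few observations to compute a statistic."""


class DegenerateDataError(MMPVError):
    """Data admit no meaningful statistic (constant vector, zero variance)."""
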