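"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`EEGAffectError` so callers can
distinguish pipeline failures from programming errors.
"""


class EEGAffectError(Exception):
    """Base class for all package errors."""


class MontageError(EEGAffectError):
    """A recording's channel set does not satisfy the montage contract."""


class ParseError(EEGAffectError):
    """A delimited input file contains a malformed cell."""


class IntegrityError(EEGAffectError):
    """A tabular artifact is internally inconsistent (ragged rows, bad labels)."""


class ConfigurationError(EEGAffectError):
    """A parameter combination violates a stage's precondition."""


class EpochingError(EEGAffectError):
    """A recording is too short for the requested window."""


class BandError(EEGAffectError):
    """A frequency band maps to no periodogram bins."""


class StatisticalError(EEGAffectError):
    """A statistical operation's sample-size precondition is violated."""
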