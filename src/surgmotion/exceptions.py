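"""Exception hierarchy for surgmotion.

All package errors derive from :class:`SurgMotionError` so callers can
catch one type. Validation vs format vs config distinctions exist because
the CLI maps them to distinct exit codes.
"""


class SurgMotionError(Exception):
    """Base class for all surgmotion errors."""


class FormatError(SurgMotionError):
    """A file does not conform to the expected tabular/XML schema."""


class ValidationError(SurgMotionError):
    """Input data violates a structural invariant (e.g. duplicate frames)."""


class InsufficientDataError(SurgMotionError):
    """A statistic was requested on a series too short to define it."""


class DegenerateInputError(SurgMotionError):
    """The input is structurally valid but degenerate for the requested
    computation (e.g. all abscissa values equal, zero median)."""


class ConfigError(SurgMotionError):
    """A simulation or analysis configuration is internally inconsistent."""
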