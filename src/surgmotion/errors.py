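"""Exception hierarchy shared across the package."""


class SurgMotionError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SurgMotionError):
    """A file does not conform to the expected tabular structure."""


class ParseError(SurgMotionError):
    """A token could not be parsed into the expected type."""


class ValidationError(SurgMotionError):
    """Parsed data violate a domain invariant."""


class DomainError(SurgMotionError, ValueError):
    """An argument lies outside an operation's mathematical domain."""


class ConfigurationError(SurgMotionError):
    """A configuration value is inconsistent or refers to missing data."""


class UnknownParticipantError(SurgMotionError):
    """Participant letter outside the known cohort."""
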