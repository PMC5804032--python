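"""Exception types shared across the package."""


class MoodCourseError(Exception):
    """Base class for package-specific errors."""


class DomainError(MoodCourseError, ValueError):
    """A value lies outside a model's state space or parameter region."""


class InsufficientDataError(MoodCourseError, ValueError):
    """Too few usable observations for the requested statistic."""


class DegenerateDataError(MoodCourseError, ValueError):
    """Data carry no information for the requested fit (e.g. constant series)."""


class UnsupportedConfigurationError(MoodCourseError, ValueError):
    """A simulation or test configuration that the method cannot honour."""
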