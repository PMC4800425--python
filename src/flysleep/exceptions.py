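"""Exception hierarchy shared across the package."""


class FlySleepError(Exception):
    """Base class for all package-specific errors."""


class DamFormatError(FlySleepError, ValueError):
    """A monitor file row could not be parsed.

    Parameters
    ----------
    message : str
        Description of the problem.
    line_number : int, optional
        1-based line number of the offending row.
    """

    def __init__(self, message, line_number=None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class DamOrderingError(FlySleepError, ValueError):
    """Monitor timestamps are not strictly increasing at a 1-minute step."""


class CapacityError(FlySleepError, ValueError):
    """More traces than a single monitor file can hold (32 channels)."""


class InsufficientDataError(FlySleepError, ValueError):
    """Too few points for the requested fit or test."""


class UnidentifiableModelError(FlySleepError, ValueError):
    """The exponent cannot be identified (fewer than 2 distinct x values)."""


class InfeasibleSummaryError(FlySleepError, ValueError):
    """An animal-period summary cannot be realized as a minute-level trace."""


class SampleSizeError(FlySleepError, ValueError):
    """Sample smaller than the minimum required by a statistical test."""


class DegenerateSampleError(FlySleepError, ValueError):
    """A sample with zero variance where variability is required."""
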