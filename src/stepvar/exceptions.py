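"""Exception hierarchy for stepvar."""


class StepvarError(Exception):
    """Base class for all stepvar errors."""


class FormatError(StepvarError, ValueError):
    """A file or stream does not conform to the expected dialect."""


class RowParseError(FormatError):
    """A single input row could not be parsed.

    Carries the 1-based line number within the source stream.
    """

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class ValidationError(StepvarError, ValueError):
    """A record or record set violates a domain invariant."""


class InsufficientDataError(StepvarError, ValueError):
    """Too few observations (or lagged pairs) for the requested statistic.

    ``n`` carries the number of usable observations/pairs actually found.
    """

    def __init__(self, message: str, n: int):
        super().__init__(message)
        self.n = n


class UndefinedEffectError(StepvarError, ValueError):
    """An effect size is undefined (e.g. all paired differences are zero)."""


class UnsupportedConfigurationError(StepvarError, ValueError):
    """A configuration outside the supported regime (e.g. closed-form
    descriptors requested for a non-stationary process)."""


class ConfigurationError(StepvarError, ValueError):
    """An inconsistent simulation or analysis configuration."""
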