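"""Exception hierarchy shared across the package."""


class RepdivError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RepdivError):
    """A clonotype table does not conform to the expected dialect."""


class RowValidationError(RepdivError):
    """A single input row failed validation; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line is not None else ""))


class DepthError(RepdivError):
    """Requested subsampling depth exceeds the sample's total UMI count."""


class UndefinedStatisticError(RepdivError):
    """A statistic is undefined for the given input (e.g. empty repertoire)."""


class ConfigurationError(RepdivError):
    """An option value or name is not recognised."""


class DomainError(RepdivError):
    """A numeric argument lies outside the statistic's domain."""


class GenerationError(RepdivError):
    """The simulator could not produce a valid clonotype within the retry cap."""
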