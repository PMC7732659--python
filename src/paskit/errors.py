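"""Exception hierarchy shared across the toolkit."""


class PasError(Exception):
    """Base class for all toolkit errors."""


class InputError(PasError, ValueError):
    """An argument violates a documented precondition."""


class DomainError(InputError):
    """A value is outside the physical/mathematical domain of an operation."""


class FormatError(PasError, ValueError):
    """A file does not conform to the documented dialect.

    ``lines`` carries the offending 1-based line numbers when known.
    """

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = lines or []


class ConfigError(PasError, ValueError):
    """A study configuration is internally inconsistent."""


class LinkageError(PasError, ValueError):
    """Records cannot be joined across tables (e.g. unknown device id)."""


class UndefinedStatisticError(PasError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class EstimationError(PasError, RuntimeError):
    """Model estimation failed; ``diagnostics`` carries optimizer detail."""

    def __init__(self, message: str, diagnostics: object = None):
        super().__init__(message)
        self.diagnostics = diagnostics
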