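"""Exception hierarchy shared across the package.

``ValidationError`` (and subclasses) signal bad *data*; the CLI maps them to
exit code 3. Plain ``ValueError``/``TypeError`` continue to signal bad
*arguments* (programming errors), and usage problems are click's domain.
"""


class SubpathnetError(Exception):
    """Base class for package-specific errors."""


class ValidationError(SubpathnetError, ValueError):
    """Input data violates a documented invariant."""


class KgmlParseError(ValidationError):
    """KGML file is not well-formed XML; message carries the byte offset."""


class NotationParseError(ValidationError):
    """Subpathway chain string does not match the notation grammar."""

    def __init__(self, message: str, column: int | None = None):
        if column is not None:
            message = f"{message} (column {column})"
        super().__init__(message)
        self.column = column


class EdgeConflictError(ValidationError):
    """The same ordered gene pair carries both an activation and an inhibition edge."""


class BudgetExceededError(SubpathnetError):
    """Path enumeration exceeded the configured path-count budget."""


class ConfigError(ValidationError):
    """Synthetic-data or pipeline configuration is inconsistent."""
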