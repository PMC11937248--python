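"""Exception hierarchy.

Every error a scenario author can trigger derives from :class:`CropgateError`
so CLI and batch callers can catch one type.
"""


class CropgateError(Exception):
    """Base class for all cropgate errors."""


class ScenarioValidationError(CropgateError, ValueError):
    """An invariant of a scenario object is violated.

    Carries the offending field name and the rule that failed so callers can
    point the user at the exact line of their scenario file.
    """

    def __init__(self, field: str, rule: str):
        self.field = field
        self.rule = rule
        super().__init__(f"invalid scenario: field '{field}' violates rule: {rule}")


class ConfigurationError(CropgateError, KeyError):
    """A factor or coefficient required by the scenario is missing from the table."""

    def __init__(self, message: str):
        super().__init__(message)
        self.message = message

    def __str__(self) -> str:  # KeyError quotes its arg; keep the plain message
        return self.message


class UnknownLabelError(CropgateError, KeyError):
    """A fixture label or lookup key does not exist."""

    def __init__(self, message: str):
        super().__init__(message)
        self.message = message

    def __str__(self) -> str:
        return self.message


class DomainError(CropgateError, ValueError):
    """A numeric argument is outside the physically meaningful domain."""
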