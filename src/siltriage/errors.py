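"""Exception hierarchy shared across the package."""


class SiltriageError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SiltriageError, ValueError):
    """A value is outside its physiologic / mathematical domain.

    Carries ``field`` so callers can report which input was bad.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class MissingDataError(SiltriageError, ValueError):
    """A required component is absent.  ``fields`` lists what is missing."""

    def __init__(self, fields):
        if isinstance(fields, str):
            fields = [fields]
        self.fields = list(fields)
        super().__init__("missing required component(s): " + ", ".join(self.fields))


class UndefinedValueError(SiltriageError, ArithmeticError):
    """A statistic is undefined for the given inputs (e.g. zero denominator)."""


class SchemaError(SiltriageError, ValueError):
    """A cohort file does not conform to the declared column schema."""
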