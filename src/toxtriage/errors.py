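"""Exception hierarchy shared across the package."""


class ToxTriageError(Exception):
    """Base class for all package errors."""


class ValidationError(ToxTriageError):
    """A value violates a domain invariant (range, pattern, units)."""


class MalformedIdentifierError(ValidationError):
    """An identifier does not match the expected pattern at all.

    Distinct from a well-formed identifier whose checksum fails, which is
    reported as an ordinary ``False`` from the validator.
    """


class SchemaError(ToxTriageError):
    """A table is missing mandatory columns; carries the missing names."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"missing mandatory column(s): {', '.join(self.missing)}")


class ParseError(ToxTriageError):
    """A cell could not be parsed; carries the row index and column."""

    def __init__(self, row: int, column: str, value: str):
        self.row = row
        self.column = column
        self.value = value
        super().__init__(f"row {row}: cannot parse {column}={value!r}")


class MissingInputError(ToxTriageError):
    """A model was asked to run without a required input (never imputed)."""


class UnsupportedChargeError(ValidationError):
    """More ionizable groups than the +/-2 species bookkeeping supports."""


class UnknownSpeciesError(KeyError, ToxTriageError):
    """Lookup of a species label absent from the QSAR registry."""

    def __init__(self, label: str, known: list[str]):
        self.label = label
        self.known = list(known)
        super().__init__(f"unknown species {label!r}; known: {', '.join(self.known)}")


class InsufficientDataError(ToxTriageError):
    """Too few observations for a fit."""


class SingularFitError(ToxTriageError):
    """Zero variance in the regressor; the OLS system is singular."""
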