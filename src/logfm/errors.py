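"""Exception hierarchy.

Three families, mirrored by CLI exit codes: parse errors (bad structures or
malformed tables), validation errors (contract violations such as missing
descriptors or empty inputs) and numerical errors (singular designs,
degenerate leverage, zero-variance responses).
"""


class LogFMError(Exception):
    """Base class for all package errors."""


class ParseError(LogFMError):
    """A structure (SMILES/SDF record) could not be parsed."""

    def __init__(self, text: str, reason: str = "unparseable structure"):
        self.text = text
        super().__init__(f"{reason}: {text!r}")


class TableFormatError(LogFMError):
    """A descriptor table violates the CSV contract (duplicate ids,
    non-numeric cells, missing header)."""


class ValidationError(LogFMError):
    """A precondition on inputs was violated."""


class MissingDescriptorError(ValidationError):
    """A required descriptor field is absent or marked missing."""

    def __init__(self, field: str, compound_id: str | None = None):
        self.field = field
        self.compound_id = compound_id
        where = f" for compound {compound_id!r}" if compound_id else ""
        super().__init__(f"required descriptor {field!r} is missing{where}")


class NumericalError(LogFMError):
    """Numerically degenerate situation (no finite answer exists)."""


class SingularityError(NumericalError):
    """Rank-deficient design matrix."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(map(str, self.columns))
        )


class LeverageError(NumericalError):
    """A leave-one-out leverage equals one: the point determines its own fit."""
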