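"""Exception hierarchy shared across the package.

Errors are split into validation errors (bad arguments, inconsistent
models — CLI exit code 2) and input errors (unreadable or malformed
files — CLI exit code 3).
"""


class HexshellError(Exception):
    """Base class for all package errors."""


class ValidationError(HexshellError):
    """Arguments or model state violate a documented precondition."""


class InputError(HexshellError):
    """A file could not be read or parsed."""


class PDBParseError(InputError):
    """Malformed PDB record; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyStructureError(InputError):
    """A structure file contained no ATOM records."""


class SelectionError(ValidationError):
    """A chain/residue/atom selection matched nothing."""


class GenerationError(ValidationError):
    """A synthetic-structure specification produced an invalid model."""


class CapacityError(ValidationError):
    """Output exceeds a fixed-width format field (e.g. PDB atom serial)."""
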