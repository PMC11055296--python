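"""Exception hierarchy for the measurement pipeline.

Every anticipated failure mode maps to one of these classes so that batch
processing can distinguish a broken specimen (geometry/validation) from a
broken input file (format/schema) and from programming errors.
"""


class TalusMorphError(Exception):
    """Base class for all package errors."""


class FormatError(TalusMorphError):
    """Unreadable or truncated input file (STL, CSV, JSON)."""


class SchemaError(TalusMorphError):
    """Well-formed file whose content violates the expected schema."""


class ValidationError(TalusMorphError):
    """Input data violating a domain invariant (empty mesh, off-surface landmark)."""


class GeometryError(TalusMorphError):
    """Degenerate geometric configuration (collinear points, empty section, ray miss)."""


class ConvergenceError(TalusMorphError):
    """Iterative fit failed to converge; carries the last iterate for diagnosis."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
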