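"""Exception hierarchy for periquant.

All domain-level failures derive from :class:`PeriquantError` so callers can
catch the package's errors with a single except clause. Validation-type
errors also derive from ``ValueError`` for ergonomic use in scripts.
"""


class PeriquantError(Exception):
    """Base class for all periquant errors."""


class ValidationError(PeriquantError, ValueError):
    """An input violates a documented precondition or invariant."""


class SchemaError(ValidationError):
    """A tabular input is missing mandatory columns or has bad types."""


class ParseError(ValidationError):
    """A file could not be parsed; message includes the offending row."""


class DegenerateGeometryError(ValidationError):
    """A geometric computation is undefined for this input (e.g. all points
    coincide with the origin, or a voxel set has rank < 3)."""


class WettingRegimeError(ValidationError):
    """A nucleation quantity was requested outside the partial-wetting
    regime where it is defined."""


class LabelNotFoundError(PeriquantError, KeyError):
    """A requested integer label is absent from a label volume."""
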