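"""Exception hierarchy for ezmap.

All errors derive from :class:`EZMapError` so callers can catch the package's
failures in one clause; the subclasses distinguish structural problems
(shapes, geometry, schemas) from empty-data conditions.
"""


class EZMapError(Exception):
    """Base class for all ezmap errors."""


class GeometryError(EZMapError, ValueError):
    """Shape/extent mismatch, out-of-bounds zone or sample location."""


class EmptyMapError(EZMapError, ValueError):
    """An operation required at least one valid measurement point."""


class ValidationError(EZMapError, ValueError):
    """Invalid parameter values or inconsistent counts."""


class SchemaError(EZMapError, ValueError):
    """A file did not match the expected column schema; names the field."""
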