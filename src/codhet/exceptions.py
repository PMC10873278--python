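"""Exception hierarchy.

All validation failures raise subclasses of :class:`CodhetError`, which also
derive from :class:`ValueError` so that callers treating the library as a
plain numerics package can catch the familiar builtin.
"""


class CodhetError(ValueError):
    """Base class for all codhet validation and input errors."""


class HierarchyError(CodhetError):
    """Malformed or structurally invalid cause hierarchy."""


class ProfileError(CodhetError):
    """Invalid mortality profile (shares off the simplex, bad bounds, ...)."""


class AlignmentError(CodhetError):
    """Cause universes of two objects cannot be aligned by id."""


class TableSchemaError(CodhetError):
    """Input table is missing required columns or has malformed rows."""
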