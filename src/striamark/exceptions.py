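"""Exception hierarchy for striamark.

All package-specific failures derive from :class:`StriamarkError` so callers
can catch the whole family with one clause.
"""


class StriamarkError(Exception):
    """Base class for all striamark errors."""


class FormatError(StriamarkError):
    """A file does not parse in the named dialect."""


class ValidationError(StriamarkError, ValueError):
    """An in-memory object violates its invariants."""


class ParameterError(StriamarkError, ValueError):
    """A parameter is outside its allowed range."""


class GeometryError(StriamarkError):
    """A mesh is folded, multivalued or degenerate in projection."""


class SizeError(StriamarkError, ValueError):
    """Too few data for the requested operation."""


class UndefinedCorrelationError(StriamarkError):
    """Normalized cross-correlation is undefined (all-zero overlap)."""


class AlignmentError(StriamarkError):
    """Sequential alignment failed (overlap collapsed at some step)."""


class DegenerateSignatureError(StriamarkError):
    """Coverage trimming left too few samples to form a signature."""


class StatisticsError(StriamarkError, ValueError):
    """A statistical routine received inadequate or degenerate input."""


class DesignError(StriamarkError, ValueError):
    """A study design constraint is violated (e.g. a knife with one mark)."""


class UnitError(StriamarkError, ValueError):
    """Incompatible physical units or sampling between operands."""
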