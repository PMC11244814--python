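"""Exception hierarchy for cocount.

All errors raised on bad user input derive from :class:`CocountError` so
callers (and the CLI) can catch one base class.
"""


class CocountError(Exception):
    """Base class for all cocount errors."""


class SchemaError(CocountError):
    """A required column or sheet is missing, or a header is malformed."""


class ValidationError(CocountError):
    """Input data violate a structural invariant (positions, segments, ranks)."""


class ParameterError(CocountError, ValueError):
    """A numeric parameter is outside its admissible range."""


class InsufficientDataError(CocountError):
    """Too few observations to compute the requested statistic."""


class DegenerateSampleError(CocountError):
    """The sample admits no finite estimate (e.g. zero-variance spacings)."""
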