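"""Exception hierarchy for the fcnef package.

All package errors derive from :class:`FcnefError` so callers can catch one
base class; the concrete subclasses distinguish malformed files, invalid
numeric parameters, and degenerate data conditions.
"""


class FcnefError(Exception):
    """Base class for all fcnef errors."""


class FormatError(FcnefError, ValueError):
    """A file does not conform to the expected on-disk format."""


class InputError(FcnefError, ValueError):
    """Well-formed input whose content cannot be processed (too short,
    over-censored, empty mask, ...)."""


class ParameterError(FcnefError, ValueError):
    """A numeric parameter is outside its valid domain."""


class ValidationError(FcnefError, ValueError):
    """A structured object violates one of its invariants."""


class DegenerateBaselineError(FcnefError, ValueError):
    """A feedback baseline cannot be formed (fewer than two trials, or
    zero variance across trial correlations)."""


class DegenerateCorrelationError(FcnefError, ValueError):
    """A correlation is undefined because one signal has zero variance."""
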