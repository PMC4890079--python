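"""Exception and warning types shared across the package."""


class CircactError(Exception):
    """Base class for all circact errors."""


class FormatError(CircactError, ValueError):
    """Input file does not conform to the accepted two-column layout."""


class ValidationError(CircactError, ValueError):
    """Record or series violates a structural invariant."""


class CircactWarning(UserWarning):
    """Base class for all circact warnings."""


class UndefinedResultWarning(CircactWarning):
    """A statistic is undefined for this input (e.g. constant signal); NaN returned."""


class PreprocessWarning(CircactWarning):
    """A preprocessing choice may bias downstream statistics."""
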