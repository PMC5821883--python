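"""Exception hierarchy for digiwell.

All errors derive from :class:`DigiwellError` so callers can catch the
package's failures with a single except clause; each also derives from the
matching builtin so they behave idiomatically.
"""


class DigiwellError(Exception):
    """Base class for all digiwell errors."""


class FormatError(DigiwellError, ValueError):
    """An input file or table does not match the expected schema."""


class DimensionError(DigiwellError, ValueError):
    """A chip table does not have one row per partition."""


class SaturationError(DigiwellError, ValueError):
    """All effective partitions are positive; the Poisson estimate diverges."""


class InsufficientDataError(DigiwellError, ValueError):
    """Not enough qualifying observations to compute the requested quantity."""


class FitError(DigiwellError, RuntimeError):
    """A model fit failed to converge or the data admit no fit."""


class UnattainableError(DigiwellError, ValueError):
    """The requested design target cannot be reached by any input."""
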