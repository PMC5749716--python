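"""Exception hierarchy for retestkit.

All errors derive from :class:`RetestkitError` so callers can catch the
package's failures with a single except clause; subclasses distinguish
format problems (bad input files), insufficient or degenerate data, and
domain errors (invalid parameter values).
"""


class RetestkitError(Exception):
    """Base class for all retestkit errors."""


class CohortFormatError(RetestkitError, ValueError):
    """An input table does not conform to the cohort schema."""


class InsufficientDataError(RetestkitError, ValueError):
    """Fewer complete observations than the analysis requires."""


class DegenerateDataError(RetestkitError, ValueError):
    """Input with no variability where variability is required (e.g. a
    constant vector handed to a normality test, or an all-identical
    test-retest table whose ICC is undefined)."""


class DomainError(RetestkitError, ValueError):
    """A parameter outside its mathematical domain (e.g. ICC > 1,
    non-positive SD)."""
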