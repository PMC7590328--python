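"""Exception hierarchy for fermfit.

All fermfit errors derive from :class:`FermfitError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
bad model inputs (``DomainError``), unusable data series (``DataError``) and
statistics that are mathematically undefined for the given vectors
(``UndefinedStatisticError``).
"""


class FermfitError(ValueError):
    """Base class for all fermfit errors."""


class DomainError(FermfitError):
    """A model input or parameter is outside its mathematical domain."""


class DataError(FermfitError):
    """An input data series is malformed or insufficient for the operation."""


class UndefinedStatisticError(FermfitError):
    """A goodness-of-fit statistic is undefined for the supplied vectors."""


class DegreesOfFreedomError(UndefinedStatisticError):
    """Too few points for the number of fitted parameters."""


class ComparisonError(FermfitError):
    """Fit results are not comparable (e.g. different data windows)."""
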