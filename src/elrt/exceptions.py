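"""Exception types shared across the package."""


class SeriesError(ValueError):
    """Base class for problems with an input series."""


class SeriesTooShortError(SeriesError):
    """Raised when a series has too few observations for the requested operation."""


class DegenerateSeriesError(SeriesError):
    """Raised when a series is constant (or otherwise carries no lag information)."""


class NonFiniteValuesError(SeriesError):
    """Raised when a series contains NaN or infinite values."""


class InfeasibleConstraintError(RuntimeError):
    """Empirical-likelihood constraint is infeasible.

    Zero lies outside the convex hull of the centered lag products, so no
    probability vector can satisfy the moment constraint and the exact EL
    statistic is undefined.
    """


class NonStationaryError(ValueError):
    """Raised when an AR(1) coefficient with ``|phi| >= 1`` is requested or fitted."""
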