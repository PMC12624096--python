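"""Ljung-Box portmanteau test, implemented from the definition.

The statistic aggregates squared sample autocorrelations over lags 1..h,

    Q = n (n + 2) * sum_{k=1}^{h} rho_k^2 / (n - k),

and is referred to a chi-square distribution with ``h - fitdf`` degrees of
freedom (``fitdf`` is the number of parameters estimated before computing
residual autocorrelations; 0 for a raw series).  The autocorrelations use
the conventional biased estimator with the full-sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateSeriesError, NonFiniteValuesError, SeriesTooShortError

__all__ = ["LBResult", "sample_acf", "ljung_box", "ljung_box_sweep"]


@dataclass(frozen=True)
class LBResult:
    """Ljung-Box test outcome at a single maximum lag ``h``."""

    Q: float
    h: int
    fitdf: int
    df: int
    p_value: float
    acf: np.ndarray
    n: int

    def to_dict(self) -> dict:
        return {
            "Q": self.Q,
            "h": self.h,
            "fitdf": self.fitdf,
            "df": self.df,
            "p_value": self.p_value,
            "n": self.n,
        }


def _validated(x) -> np.ndarray:
    values = np.asarray(getattr(x, "values", x), dtype=float)
    if values.ndim != 1:
        raise ValueError(f"expected a one-dimensional series, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise NonFiniteValuesError("series contains non-finite values")
    return values


def _acf_upto(values: np.ndarray, h: int) -> np.ndarray:
    d = values - values.mean()
    denom = float(np.sum(d**2))
    if denom == 0.0:
        raise DegenerateSeriesError("constant series has no defined autocorrelation")
    return np.array([float(np.sum(d[k:] * d[: len(d) - k])) / denom for k in range(1, h + 1)])


def sample_acf(x, k: int) -> float:
    """Sample autocorrelation at lag ``k`` (biased estimator, full-sample mean)."""
    values = _validated(x)
    n = values.shape[0]
    if not 0 <= k < n:
        raise ValueError(f"lag must satisfy 0 <= k < n = {n}, got {k}")
    if k == 0:
        d = values - values.mean()
        if np.sum(d**2) == 0.0:
            raise DegenerateSeriesError("constant series has no defined autocorrelation")
        return 1.0
    return float(_acf_upto(values, k)[-1])


def ljung_box(x, h: int = 1, fitdf: int = 0) -> LBResult:
    """Ljung-Box Q test on ``x`` over lags 1..h.

    Use ``fitdf=0`` for a raw series (degrees of freedom = h) and
    ``fitdf=p`` when ``x`` are residuals of a fitted model with ``p``
    autoregressive/moving-average parameters (requires ``h > fitdf``).
    """
    values = _validated(x)
    n = values.shape[0]
    if not 1 <= h < n:
        raise ValueError(f"number of lags must satisfy 1 <= h < n = {n}, got {h}")
    if fitdf < 0:
        raise ValueError("fitdf must be nonnegative")
    df = h - fitdf
    if df < 1:
        raise ValueError(f"h ({h}) must exceed fitdf ({fitdf})")
    acf = _acf_upto(values, h)
    Q = float(n * (n + 2) * np.sum(acf**2 / (n - np.arange(1, h + 1))))
    return LBResult(
        Q=Q,
        h=h,
        fitdf=fitdf,
        df=df,
        p_value=float(stats.chi2.sf(Q, df=df)),
        acf=acf,
        n=n,
    )


def ljung_box_sweep(x, h_max: int = 10, fitdf: int = 0) -> list[LBResult]:
    """Sensitivity sweep: the Ljung-Box test at every lag ``fitdf+1 .. h_max``.

    The appropriate maximum lag for a portmanteau test is a judgement call;
    the sweep makes conclusions checkable across the usual range instead of
    resting on a single choice.
    """
    values = _validated(x)
    if h_max >= values.shape[0]:
        raise ValueError("h_max must be smaller than the series length")
    return [ljung_box(values, h=h, fitdf=fitdf) for h in range(fitdf + 1, h_max + 1)]
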