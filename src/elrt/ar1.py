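"""AR(1) process machinery: simulation, moments, estimation, forecasting.

The model is ``X_t = mu + phi (X_{t-1} - mu) + eps_t`` with i.i.d. Gaussian
innovations of variance ``sigma2`` and ``|phi| < 1``.  Its autocorrelation
function is geometric, ``rho_h = phi**h``, and the stationary variance is
``sigma2 / (1 - phi**2)``.

Estimation is exposed statsmodels-style: build :class:`AR1Model` from the
data and call :meth:`AR1Model.fit`, which returns an :class:`AR1Results`
carrying the estimates, residual diagnostics, a ``summary()`` table and a
``forecast()`` method.  Thin functional wrappers (:func:`fit_ar1`,
:func:`forecast_ar1`) mirror the same operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateSeriesError, NonStationaryError, SeriesTooShortError

__all__ = [
    "simulate_ar1",
    "theoretical_acf",
    "AR1Model",
    "AR1Results",
    "ForecastResult",
    "fit_ar1",
    "forecast_ar1",
]


def simulate_ar1(
    n: int,
    phi: float,
    sigma: float = 1.0,
    seed=None,
    burn_in: int = 100,
    mu: float = 0.0,
) -> np.ndarray:
    """Simulate a stationary Gaussian AR(1) path of length ``n``.

    The recursion starts from a draw of the stationary distribution
    (variance ``sigma**2 / (1 - phi**2)``) and additionally discards
    ``burn_in`` warm-up steps, emulating standard ARIMA simulators.
    ``seed`` may be an integer, a ``numpy.random.Generator`` or a
    ``SeedSequence``; a fixed seed reproduces the path bit for bit.
    """
    if abs(phi) >= 1.0:
        raise NonStationaryError(f"|phi| must be < 1 for a stationary AR(1), got {phi}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma <= 0.0:
        raise ValueError("sigma must be positive")
    if burn_in < 0:
        raise ValueError("burn_in must be nonnegative")
    rng = np.random.default_rng(seed)
    total = n + burn_in
    eps = rng.standard_normal(total) * sigma
    x = np.empty(total)
    x[0] = eps[0] / np.sqrt(1.0 - phi * phi)
    for t in range(1, total):
        x[t] = phi * x[t - 1] + eps[t]
    return mu + x[burn_in:]


def theoretical_acf(phi: float, h: int) -> float:
    """Theoretical AR(1) autocorrelation at lag ``h``: ``phi**h``.

    Decays geometrically; for negative ``phi`` the signs alternate.
    """
    if abs(phi) >= 1.0:
        raise NonStationaryError(f"|phi| must be < 1, got {phi}")
    if h < 0:
        raise ValueError("lag must be nonnegative")
    return float(phi**h)


@dataclass(frozen=True)
class ForecastResult:
    """Multi-step AR(1) forecast with symmetric normal prediction intervals.

    Plug-in intervals: parameter-estimation uncertainty is not propagated,
    only innovation uncertainty accumulated over the horizon.
    """

    horizon: int
    points: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": np.arange(1, self.horizon + 1),
                "point": self.points,
                "se": self.se,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


@dataclass(frozen=True)
class AR1Results:
    """Fitted AR(1) parameters plus enough context to forecast from.

    Attributes
    ----------
    phi : float
        Autoregressive coefficient, ``|phi| < 1``.
    mu : float
        Process mean (0 when the model was fitted without demeaning).
    sigma2 : float
        Innovation variance.
    method : str
        One of ``yule_walker``, ``cls``, ``mle``.
    n : int
        Number of observations used.
    last_value : float
        Final observation, the forecasting origin.
    resid : ndarray
        One-step in-sample residuals ``x_t - mu - phi (x_{t-1} - mu)``.
    """

    phi: float
    mu: float
    sigma2: float
    method: str
    n: int
    last_value: float
    resid: np.ndarray

    def forecast(self, horizon: int, level: float = 0.95, last_value: float | None = None) -> ForecastResult:
        return forecast_ar1(self, last_value=last_value, horizon=horizon, level=level)

    def summary(self) -> str:
        lines = [
            "AR(1) model results",
            "===================",
            f"method:      {self.method}",
            f"nobs:        {self.n}",
            f"phi:         {self.phi:.6f}",
            f"mu:          {self.mu:.6f}",
            f"sigma2:      {self.sigma2:.6f}",
            f"stationary variance: {self.sigma2 / (1 - self.phi**2):.6f}",
        ]
        return "\n".join(lines)


class AR1Model:
    """Gaussian AR(1) model for a univariate series.

    Parameters
    ----------
    endog : array_like or pandas.Series
        Observed series, at least 4 non-constant values.
    demean : bool
        When true (application-style data) the process mean is estimated;
        when false the model is the zero-mean recursion used in simulation
        studies.
    """

    def __init__(self, endog, demean: bool = True):
        values = np.asarray(getattr(endog, "values", endog), dtype=float)
        if values.ndim != 1:
            raise ValueError("endog must be one-dimensional")
        if values.shape[0] < 4:
            raise SeriesTooShortError(f"need at least 4 observations, got {values.shape[0]}")
        if not np.all(np.isfinite(values)):
            raise ValueError("endog contains non-finite values")
        if np.ptp(values) == 0.0:
            raise DegenerateSeriesError("constant series cannot be fitted")
        self.endog = values
        self.demean = demean
        self.nobs = values.shape[0]

    @classmethod
    def from_dataframe(cls, data, column: str, demean: bool = True) -> "AR1Model":
        return cls(data[column], demean=demean)

    def fit(self, method: str = "mle", clip: bool = False) -> AR1Results:
        """Estimate ``(phi, mu, sigma2)``.

        ``yule_walker`` equates phi-hat to the lag-1 sample autocorrelation;
        ``cls`` minimizes the conditional sum of squares (OLS of ``x_t`` on
        ``x_{t-1}``); ``mle`` maximizes the exact Gaussian likelihood via
        statsmodels.  A non-stationary estimate raises unless ``clip`` is
        set, in which case it is pulled just inside the unit interval.
        """
        x = self.endog
        mu = float(x.mean()) if self.demean else 0.0
        d = x - mu
        if method == "yule_walker":
            # equals sample_acf(x, 1) when demean=True
            phi = float(np.sum(d[1:] * d[:-1]) / np.sum(d * d))
        elif method == "cls":
            phi = float(np.sum(d[1:] * d[:-1]) / np.sum(d[:-1] ** 2))
        elif method == "mle":
            from statsmodels.tsa.statespace.sarimax import SARIMAX

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm_fit = SARIMAX(
                    x,
                    order=(1, 0, 0),
                    trend="c" if self.demean else "n",
                ).fit(disp=False)
            phi = float(sm_fit.params[1] if self.demean else sm_fit.params[0])
            if self.demean:
                # SARIMAX 'c' trend parameter is the regression intercept
                phi_safe = phi if abs(phi) < 1 else np.sign(phi) * 0.999999
                mu = float(sm_fit.params[0] / (1.0 - phi_safe))
                d = x - mu
        else:
            raise ValueError(f"unknown method {method!r}")

        if abs(phi) >= 1.0:
            if not clip:
                raise NonStationaryError(
                    f"fitted |phi| = {abs(phi):.4f} >= 1; pass clip=True to force stationarity"
                )
            phi = float(np.sign(phi)) * (1.0 - 1e-6)

        resid = d[1:] - phi * d[:-1]
        sigma2 = float(np.mean(resid**2))
        if sigma2 <= 0.0:
            raise DegenerateSeriesError("zero residual variance")
        return AR1Results(
            phi=float(phi),
            mu=mu,
            sigma2=sigma2,
            method=method,
            n=self.nobs,
            last_value=float(x[-1]),
            resid=resid,
        )


def fit_ar1(x, method: str = "mle", demean: bool = True) -> AR1Results:
    """Functional wrapper: ``AR1Model(x, demean=demean).fit(method)``."""
    return AR1Model(x, demean=demean).fit(method=method)


def forecast_ar1(
    fit: AR1Results,
    last_value: float | None = None,
    horizon: int = 1,
    level: float = 0.95,
) -> ForecastResult:
    """h-step-ahead AR(1) forecasts with plug-in normal prediction intervals.

    Point forecasts follow ``mu + phi**h (x_n - mu)``; the h-step forecast
    variance is ``sigma2 * sum_{j=0}^{h-1} phi**(2j)``, which grows to the
    stationary variance as the horizon lengthens.
    """
    if abs(fit.phi) >= 1.0:
        raise NonStationaryError("cannot forecast from a non-stationary fit")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    origin = fit.last_value if last_value is None else float(last_value)
    steps = np.arange(1, horizon + 1)
    points = fit.mu + fit.phi**steps * (origin - fit.mu)
    var = fit.sigma2 * np.cumsum(fit.phi ** (2 * (steps - 1)))
    se = np.sqrt(var)
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return ForecastResult(
        horizon=horizon,
        points=points,
        se=se,
        lower=points - z * se,
        upper=points + z * se,
        level=level,
    )
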