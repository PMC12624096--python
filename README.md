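# elrt — empirical likelihood ratio testing for AR(1) identification

`elrt` is a toolkit for deciding whether a univariate time series follows a
first-order autoregressive, AR(1), structure — a question that arises
constantly in environmental-exposure forecasting, where pollutant records
(PM2.5 in particular) are short, strongly autocorrelated and non-Gaussian
enough that the usual diagnostics (ACF/PACF plots, portmanteau tests) feel
subjective. The package provides:

- a nonparametric **empirical likelihood ratio test (ELRT)** for lag-1
  autocorrelation, in both exact (constrained-optimization) and closed-form
  variants;
- a self-contained **Ljung–Box** comparator with a lag-sensitivity sweep;
- **AR(1) machinery**: stationary simulation, Yule–Walker / conditional
  least squares / maximum-likelihood estimation, multi-step forecasting with
  prediction intervals;
- a seeded **Monte Carlo engine** for empirical size and power studies;
- an **air-quality pipeline** that preprocesses a PM2.5 record (LOCF
  imputation, weekly aggregation, box-plot outlier screen), tests it, fits
  an AR(1), forecasts, and labels forecasts with Indian national AQI
  categories, plus a calibrated synthetic PM2.5 generator for testing.

## The test

Given observations x₁,…,xₙ with mean x̄, form the m = n−1 centered lag-1
cross-products

```
c_t = (x_t − x̄)(x_{t−1} − x̄),   t = 2,…,n.
```

Under H₀ (no lag-1 dependence) E[c_t] ≈ 0, so the empirical likelihood ratio
places weights p_t on the c_t and maximizes ∏ m·p_t subject to Σp_t = 1 and
Σp_t c_t = 0:

```
−2 log R = 2 Σ log(1 + η c_t),   η solving Σ c_t / (1 + η c_t) = 0
```

(exact variant), with the second-order expansion

```
−2 log R ≈ (Σ c_t)² / Σ c_t²
```

as the always-defined closed form. Both are asymptotically χ²₁ under H₀;
H₀ is rejected when the statistic exceeds the χ²₁ upper-α quantile
(3.84 at α = 0.05). The statistic is invariant to location and scale
changes of the series. When zero lies outside the convex hull of the c_t
the exact constraint is infeasible; `method="auto"` then falls back to the
closed form and flags `feasible=False`.

## Worked example

```python
from elrt import simulate_ar1, elrt_test, ljung_box, AR1Model

x = simulate_ar1(100, phi=0.6, seed=42)          # stationary Gaussian AR(1)

res = elrt_test(x, alpha=0.05, method="auto")
print(res.statistic, res.p_value, res.reject)     # 43.8994 3.46e-11 True

lb = ljung_box(x, h=1)
print(lb.Q, lb.p_value)                           # 36.3174 1.68e-09

fit = AR1Model(x, demean=True).fit(method="mle")
print(fit.summary())
# phi:         0.595004
# sigma2:      0.958448  (stationary variance 1.483733)

print(fit.forecast(horizon=3, level=0.95).to_frame().round(3))
#    step  point     se  lower  upper
# 0     1 -0.204  0.979 -2.123  1.715
# 1     2 -0.149  1.139 -2.382  2.084
# 2     3 -0.117  1.191 -2.451  2.217
```

Both tests correctly flag the strong lag-1 dependence (statistics far above
3.84), the maximum-likelihood fit recovers φ ≈ 0.6, and the forecast
standard errors grow toward the stationary standard deviation as the
horizon lengthens.

The same workflow from the shell, end to end on a synthetic weekly PM2.5
record (156 weeks, ~2% missing, lag-1 autocorrelation ≈ 0.856):

```
elrt synth --seed 3 --out pm25.csv
elrt forecast pm25.csv --horizon 28 --out report.json --forecast-csv fc.csv
```

On this record the pipeline reports an ELRT statistic of ≈ 144 (p < 0.001,
strong evidence of AR(1) structure), a fitted φ ≈ 0.85, a residual
Ljung–Box p ≈ 0.40 (the AR(1) fit is adequate), and 28 weekly forecasts
whose AQI labels move from "Very Poor"/"Poor" in the first winter weeks to
"Moderately Polluted" as the seasonal level declines.

Monte Carlo studies run from a YAML design file:

```
elrt mc-power design.yaml --out rates.csv --plot-dir figures/
```

where `design.yaml` might contain
`{tests: [elrt_exact, elrt_approx, lb], n_grid: [20, 50], phi_grid: [0.0, 0.3, 0.6, 0.9], reps: 5000, seed: 1}`.
The output is a tidy table of rejection rates with Monte Carlo standard
errors, one row per (test, n, φ); rows with φ = 0 are empirical sizes.

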