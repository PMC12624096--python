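"""Unit and property tests for the empirical likelihood core."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from elrt.elcore import (
    centered_lag_products,
    el_solve_weights,
    elrt_statistic_approx,
    elrt_statistic_exact,
    elrt_test,
)
from elrt.exceptions import (
    DegenerateSeriesError,
    InfeasibleConstraintError,
    NonFiniteValuesError,
    SeriesTooShortError,
)


@pytest.mark.parametrize(
    "x, expected_c",
    [
        ([1, 2, 3, 4], [0.75, -0.25, 0.75]),
        ([5, 5, 5, 5], [0.0, 0.0, 0.0]),
        ([1, -1, 1, -1], [-1.0, -1.0, -1.0]),
    ],
)
def test_centered_lag_products_worked_examples(x, expected_c):
    lp = centered_lag_products(x)
    np.testing.assert_allclose(lp.c, expected_c, atol=1e-14)
    assert lp.m == len(x) - 1
    assert lp.center == pytest.approx(np.mean(x))


def test_lag_products_input_validation():
    with pytest.raises(SeriesTooShortError):
        centered_lag_products([1.0, 2.0])
    with pytest.raises(NonFiniteValuesError):
        centered_lag_products([1.0, np.nan, 2.0])
    with pytest.raises(NonFiniteValuesError):
        centered_lag_products([1.0, np.inf, 2.0, 3.0])


def test_lag_products_location_invariant_scale_quadratic(rng):
    x = rng.standard_normal(40)
    base = centered_lag_products(x).c
    shifted = centered_lag_products(x + 17.3).c
    scaled = centered_lag_products(3.0 * x).c
    np.testing.assert_allclose(shifted, base, atol=1e-10)
    np.testing.assert_allclose(scaled, 9.0 * base, rtol=1e-12)


@pytest.mark.parametrize(
    "c, expected",
    [
        ([0.75, -0.25, 0.75], 1.25**2 / 1.1875),
        ([1.0, -1.0], 0.0),
        ([2.0, 2.0, 2.0, 2.0, 2.0], 5.0),  # m identical terms -> m
    ],
)
def test_approx_statistic_worked_examples(c, expected):
    assert elrt_statistic_approx(np.array(c)) == pytest.approx(expected, abs=1e-12)


def test_approx_statistic_degenerate_input():
    with pytest.raises(DegenerateSeriesError):
        elrt_statistic_approx(np.zeros(5))


@pytest.mark.parametrize(
    "c, exp_eta, exp_w",
    [
        ([1.0, -1.0], 0.0, [0.5, 0.5]),
        ([2.0, -1.0], 0.25, [1 / 3, 2 / 3]),
        ([1.0, -2.0, 1.0], 0.0, [1 / 3, 1 / 3, 1 / 3]),  # sum already zero
    ],
)
def test_el_solve_weights_worked_examples(c, exp_eta, exp_w):
    eta, w = el_solve_weights(np.array(c))
    assert eta == pytest.approx(exp_eta, abs=1e-9)
    np.testing.assert_allclose(w, exp_w, atol=1e-9)


def test_el_weights_satisfy_constraints(rng):
    for _ in range(25):
        c = rng.standard_normal(rng.integers(5, 60))
        if not (c.min() < 0 < c.max()):
            continue
        eta, w = el_solve_weights(c)
        assert np.all(w > 0)
        assert abs(w.sum() - 1.0) < 1e-10
        assert abs(np.dot(w, c)) < 1e-8 * np.max(np.abs(c))


def _oracle_eta(c):
    """Independent solver for m <= 3: analytic for m=2, refined grid for m=3."""
    c = np.asarray(c, dtype=float)
    if len(c) == 2:
        return -(c[0] + c[1]) / (2.0 * c[0] * c[1])
    lo, hi = -1.0 / c.max(), -1.0 / c.min()
    a, b = lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo)
    for _ in range(8):
        grid = np.linspace(a, b, 20001)
        vals = (c[None, :] / (1.0 + grid[:, None] * c[None, :])).sum(axis=1)
        i = int(np.argmin(np.abs(vals)))
        a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    return 0.5 * (a + b)


def test_solver_matches_brute_force_oracle_small_m(rng):
    cases = [np.array([2.0, -1.0]), np.array([0.3, -5.0])]
    for _ in range(10):
        c = rng.standard_normal(3)
        if c.min() < 0 < c.max():
            cases.append(c)
    for c in cases:
        eta, _ = el_solve_weights(c)
        assert eta == pytest.approx(_oracle_eta(c), abs=1e-8)


def test_exact_statistic_worked_examples():
    expected = 2 * (np.log(1.5) + np.log(0.75))
    assert elrt_statistic_exact(np.array([2.0, -1.0])) == pytest.approx(expected, abs=1e-10)
    assert elrt_statistic_exact(np.array([1.5, -1.0, -0.5])) == pytest.approx(0.0, abs=1e-12)


def test_exact_statistic_infeasible_raises():
    with pytest.raises(InfeasibleConstraintError):
        elrt_statistic_exact(np.array([1.0, 2.0, 3.0]))


def test_exact_close_to_approx_for_large_m(rng):
    c = rng.standard_normal(500)
    exact = elrt_statistic_exact(c)
    approx = elrt_statistic_approx(c)
    assert abs(exact - approx) < 0.05 * max(approx, 1.0)


def test_exact_approx_agreement_improves_with_n(rng):
    gaps = []
    for n in (50, 200, 1000):
        diffs = []
        for _ in range(30):
            x = rng.standard_normal(n)
            c = centered_lag_products(x)
            diffs.append(abs(elrt_statistic_exact(c) - elrt_statistic_approx(c)))
        gaps.append(np.mean(diffs))
    assert gaps[0] > gaps[1] > gaps[2]


@given(
    a=st.floats(-50, 50),
    b=st.floats(0.01, 100),
    seed=st.integers(0, 10_000),
)
def test_statistic_location_scale_invariance(a, b, seed):
    x = np.random.default_rng(seed).standard_normal(30)
    base_approx = elrt_statistic_approx(centered_lag_products(x))
    base_exact = elrt_statistic_exact(centered_lag_products(x))
    y = a + b * x
    assert elrt_statistic_approx(centered_lag_products(y)) == pytest.approx(base_approx, rel=1e-10, abs=1e-10)
    assert elrt_statistic_exact(centered_lag_products(y)) == pytest.approx(base_exact, rel=1e-10, abs=1e-10)


def test_statistic_increases_with_constraint_sum_at_fixed_energy():
    # |sum c| grows while sum c^2 stays fixed: evidence must increase.
    thetas = np.linspace(0.05, np.pi / 4, 9)  # sum c = r(cos t + sin t) increasing
    stats_ = [elrt_statistic_approx(np.array([np.cos(t), np.sin(t)]) * 2.0 - 0)  # noqa: E501
              for t in thetas]
    sums = [2.0 * (np.cos(t) + np.sin(t)) for t in thetas]
    assert np.all(np.diff(sums) > 0)
    assert np.all(np.diff(stats_) > 0)


def test_elrt_test_assembles_result():
    res = elrt_test([1, 2, 3, 4], alpha=0.05, method="approx")
    assert res.statistic == pytest.approx(1.3157894736842106, abs=1e-9)
    assert not res.reject
    assert res.n == 4
    assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 1))
    assert res.constraint_sum == pytest.approx(1.25)


def test_elrt_test_boundary_and_zero_statistic(rng):
    # strict inequality at the critical value: a statistic exactly at the
    # chi2(1) 0.95 quantile must not reject
    crit = stats.chi2.ppf(0.95, 1)
    x = rng.standard_normal(100)
    res = elrt_test(x, method="approx")
    assert res.reject == (res.statistic > crit)
    # zero statistic -> p-value 1, no rejection (lag products sum to zero)
    res0 = elrt_test([1.0, 2.0, -2.0, -1.0, 0.0], method="approx")
    assert res0.statistic == pytest.approx(0.0, abs=1e-14)
    assert res0.p_value == pytest.approx(1.0)
    assert not res0.reject


def test_elrt_test_validation_and_degenerate():
    with pytest.raises(SeriesTooShortError):
        elrt_test([1.0, 2.0])
    with pytest.raises(DegenerateSeriesError):
        elrt_test([3.0, 3.0, 3.0, 3.0])
    with pytest.raises(ValueError):
        elrt_test([1, 2, 3, 4], alpha=1.5)
    with pytest.raises(ValueError):
        elrt_test([1, 2, 3, 4], method="bogus")


def test_auto_falls_back_when_infeasible():
    # [0, 3, 0]: both centered lag products are negative, so the exact EL
    # constraint is infeasible
    res = elrt_test([0.0, 3.0, 0.0], method="auto")
    assert not res.feasible
    assert res.method == "approx"
    with pytest.raises(InfeasibleConstraintError):
        elrt_test([0.0, 3.0, 0.0], method="exact")


def test_exact_result_carries_weights(rng):
    x = rng.standard_normal(50)
    res = elrt_test(x, method="exact")
    assert res.feasible and res.method == "exact"
    assert res.weights is not None and res.eta is not None
    assert abs(res.weights.sum() - 1.0) < 1e-10
    c = centered_lag_products(x).c
    assert abs(np.dot(res.weights, c)) < 1e-8 * np.max(np.abs(c))
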