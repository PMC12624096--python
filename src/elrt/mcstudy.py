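"""Seeded Monte Carlo engine for empirical size and power of the tests.

A design is a grid over tests x sample sizes x AR(1) coefficients.  For
every ``(n, phi)`` cell the engine simulates ``reps`` independent stationary
Gaussian AR(1) series (white noise when ``phi = 0``), applies each requested
test to the *same* batch (a paired comparison), and records the fraction of
replications whose statistic exceeds its chi-square critical value.  Rows
with ``phi = 0`` are empirical sizes; the rest are empirical powers.

Reproducibility: each cell draws from a ``numpy.random.SeedSequence`` keyed
on ``(master seed, n, round(1000 phi))``, so a single cell re-run in
isolation reproduces the corresponding row of a full-grid run exactly.

The test statistics are evaluated with vectorized batch kernels; a unit test
pins the kernels to the per-series public functions in ``elcore`` and
``portmanteau``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["MCDesign", "empirical_size", "empirical_power", "run_design", "plot_rejection_curves"]

KNOWN_TESTS = ("elrt_exact", "elrt_approx", "lb")

DEFAULT_N_GRID = (20, 30, 50, 80, 100, 200)
DEFAULT_PHI_GRID = tuple(round(0.1 * k, 1) for k in range(10))


@dataclass(frozen=True)
class MCDesign:
    """Specification of a size/power study.

    Defaults reproduce the headline study: n in {20, 30, 50, 80, 100, 200},
    phi from 0 to 0.9 in steps of 0.1, 5000 replications at nominal level
    0.05, with the Ljung-Box comparator evaluated at ``lb_h`` lags on the
    raw series.
    """

    tests: tuple = ("elrt_exact", "elrt_approx", "lb")
    n_grid: tuple = DEFAULT_N_GRID
    phi_grid: tuple = DEFAULT_PHI_GRID
    reps: int = 5000
    alpha: float = 0.05
    seed: int = 0
    lb_h: int = 1
    burn_in: int = 100

    def __post_init__(self):
        object.__setattr__(self, "tests", tuple(self.tests))
        object.__setattr__(self, "n_grid", tuple(int(n) for n in self.n_grid))
        object.__setattr__(self, "phi_grid", tuple(float(p) for p in self.phi_grid))
        unknown = set(self.tests) - set(KNOWN_TESTS)
        if unknown:
            raise ValueError(f"unknown tests: {sorted(unknown)}; choose from {KNOWN_TESTS}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if any(abs(p) >= 1.0 for p in self.phi_grid):
            raise ValueError("all |phi| must be < 1")
        if any(n < 4 for n in self.n_grid):
            raise ValueError("all n must be >= 4")
        if self.lb_h < 1:
            raise ValueError("lb_h must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_config(cls, path) -> "MCDesign":
        """Load a design from a YAML config file (keys = field names)."""
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _cell_rng(seed: int, n: int, phi: float) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(n), int(round(1000 * phi)))))


def simulate_batch(rng: np.random.Generator, reps: int, n: int, phi: float, burn_in: int = 100) -> np.ndarray:
    """Simulate ``reps`` stationary AR(1) series of length ``n`` as a 2-D array."""
    total = n + burn_in
    eps = rng.standard_normal((reps, total))
    x = np.empty((reps, total))
    x[:, 0] = eps[:, 0] / np.sqrt(1.0 - phi * phi)
    for t in range(1, total):
        x[:, t] = phi * x[:, t - 1] + eps[:, t]
    return x[:, burn_in:]


def _lag_products_batch(x: np.ndarray) -> np.ndarray:
    d = x - x.mean(axis=1, keepdims=True)
    return d[:, 1:] * d[:, :-1]


def _elrt_approx_batch(c: np.ndarray) -> np.ndarray:
    return c.sum(axis=1) ** 2 / (c**2).sum(axis=1)


def _elrt_exact_batch(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact EL statistic per row; infeasible rows fall back to the closed form.

    Returns ``(statistics, feasible_mask)``.
    """
    reps = c.shape[0]
    out = np.empty(reps)
    feasible = np.ones(reps, dtype=bool)
    approx = _elrt_approx_batch(c)
    for i in range(reps):
        ci = c[i]
        total = ci.sum()
        if total == 0.0:
            out[i] = 0.0
            continue
        cmin, cmax = ci.min(), ci.max()
        if not (cmin < 0.0 < cmax):
            feasible[i] = False
            out[i] = approx[i]
            continue
        lo, hi = -1.0 / cmax, -1.0 / cmin
        pad = 1e-12 * (hi - lo)
        eta = optimize.brentq(
            lambda e: float(np.sum(ci / (1.0 + e * ci))),
            lo + pad,
            hi - pad,
            xtol=1e-13,
            maxiter=200,
        )
        out[i] = 2.0 * np.sum(np.log1p(eta * ci))
    return out, feasible


def _lb_batch(x: np.ndarray, h: int) -> np.ndarray:
    """Ljung-Box Q at maximum lag ``h`` for every row of ``x``."""
    n = x.shape[1]
    d = x - x.mean(axis=1, keepdims=True)
    denom = (d**2).sum(axis=1)
    acc = np.zeros(x.shape[0])
    for k in range(1, h + 1):
        rk = (d[:, k:] * d[:, : n - k]).sum(axis=1) / denom
        acc = acc + rk**2 / (n - k)
    return n * (n + 2) * acc


def _run_cell(design: MCDesign, n: int, phi: float) -> list[dict]:
    rng = _cell_rng(design.seed, n, phi)
    x = simulate_batch(rng, design.reps, n, phi, burn_in=design.burn_in)
    crit1 = float(stats.chi2.ppf(1.0 - design.alpha, df=1))
    rows = []
    c = None
    exact_stats = None
    feasible = None
    for test in design.tests:
        extra: dict = {}
        if test in ("elrt_exact", "elrt_approx") and c is None:
            c = _lag_products_batch(x)
        if test == "elrt_approx":
            rejects = _elrt_approx_batch(c) > crit1
        elif test == "elrt_exact":
            if exact_stats is None:
                exact_stats, feasible = _elrt_exact_batch(c)
            rejects = exact_stats > crit1
            extra["infeasible_rate"] = float(1.0 - feasible.mean())
        else:  # lb
            crit_h = float(stats.chi2.ppf(1.0 - design.alpha, df=design.lb_h))
            rejects = _lb_batch(x, design.lb_h) > crit_h
            extra["lb_h"] = design.lb_h
        rejections = int(rejects.sum())
        rate = rejections / design.reps
        rows.append(
            {
                "test": test,
                "n": n,
                "phi": phi,
                "alpha": design.alpha,
                "reps": design.reps,
                "seed": design.seed,
                "rejections": rejections,
                "rate": rate,
                "mc_se": float(np.sqrt(rate * (1.0 - rate) / design.reps)),
                **extra,
            }
        )
    return rows


def empirical_size(test: str, n: int, reps: int, alpha: float, seed: int, lb_h: int = 1) -> dict:
    """Empirical type-I error row: rejection fraction over white-noise replications."""
    design = MCDesign(tests=(test,), n_grid=(n,), phi_grid=(0.0,), reps=reps, alpha=alpha, seed=seed, lb_h=lb_h)
    return _run_cell(design, n, 0.0)[0]


def empirical_power(test: str, n: int, phi: float, reps: int, alpha: float, seed: int, lb_h: int = 1) -> dict:
    """Empirical power row: rejection fraction under an AR(1) alternative (``phi > 0``)."""
    if not 0.0 < phi < 1.0:
        raise ValueError("power requires 0 < phi < 1; use empirical_size for phi = 0")
    design = MCDesign(tests=(test,), n_grid=(n,), phi_grid=(phi,), reps=reps, alpha=alpha, seed=seed, lb_h=lb_h)
    return _run_cell(design, n, phi)[0]


def run_design(design: MCDesign) -> pd.DataFrame:
    """Run the full grid; one tidy row per (test, n, phi)."""
    rows: list[dict] = []
    for n in design.n_grid:
        for phi in design.phi_grid:
            rows.extend(_run_cell(design, n, phi))
    return pd.DataFrame(rows)


def plot_rejection_curves(result: pd.DataFrame, out_dir, formats: tuple = ("png",)) -> list:
    """One rejection-rate-vs-phi figure per sample size, tests overlaid."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for n, group in result.groupby("n"):
        fig, ax = plt.subplots(figsize=(6, 4))
        for test, sub in group.groupby("test"):
            sub = sub.sort_values("phi")
            ax.plot(sub["phi"], sub["rate"], marker="o", label=test)
        ax.axhline(group["alpha"].iloc[0], color="grey", ls="--", lw=0.8)
        ax.set_xlabel("AR(1) coefficient phi")
        ax.set_ylabel("rejection rate")
        ax.set_title(f"Rejection rates, n = {n}")
        ax.legend()
        fig.tight_layout()
        for fmt in formats:
            path = out_dir / f"rejection_rates_n{n}.{fmt}"
            fig.savefig(path, dpi=120)
            written.append(path)
        plt.close(fig)
    return written
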