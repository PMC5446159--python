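"""Benchmark metrics, greedy outlier removal, database subsampling, and
constrained Hill-curve extrapolation of performance versus database size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares


@dataclass
class BenchmarkResult:
    R: float
    rho: float
    rmse: float
    accuracy: float
    n: int
    R_out: float | None = None
    rho_out: float | None = None
    n_removed: int = 0


def _regression_rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    """RMS residual of obs regressed linearly on pred (intercept-only fit
    when pred is constant)."""
    if np.ptp(pred) == 0:
        resid = obs - obs.mean()
    else:
        slope, intercept = np.polyfit(pred, obs, 1)
        resid = obs - (slope * pred + intercept)
    return float(np.sqrt(np.mean(resid**2)))


def _sign_accuracy(pred: np.ndarray, obs: np.ndarray) -> float:
    """Fraction of matching signs; exact zeros match only exact zeros."""
    return float(np.mean(np.sign(pred) == np.sign(obs)))


def benchmark(
    pred: Sequence[float],
    obs: Sequence[float],
    outlier_frac: float | None = None,
) -> BenchmarkResult:
    """Pearson R, Spearman rho (average ranks on ties), regression RMSE and
    sign accuracy; optionally also R and rho after greedy removal of the
    most outlying fraction of points (each metric optimized separately).

    A constant prediction vector leaves R and rho undefined (NaN); the
    RMSE is still reported from an intercept-only fit.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(pred) < 3:
        raise ValueError("need matching 1-d vectors of length >= 3")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        r = rho = float("nan")
    else:
        r = float(stats.pearsonr(pred, obs).statistic)
        rho = float(stats.spearmanr(pred, obs).statistic)
    res = BenchmarkResult(
        R=r,
        rho=rho,
        rmse=_regression_rmse(pred, obs),
        accuracy=_sign_accuracy(pred, obs),
        n=len(pred),
    )
    if outlier_frac:
        removed_r = remove_outliers(pred, obs, outlier_frac, metric="pearson")
        keep = np.setdiff1d(np.arange(len(pred)), removed_r)
        res.R_out = float(stats.pearsonr(pred[keep], obs[keep]).statistic)
        removed_s = remove_outliers(pred, obs, outlier_frac, metric="spearman")
        keep = np.setdiff1d(np.arange(len(pred)), removed_s)
        res.rho_out = float(stats.spearmanr(pred[keep], obs[keep]).statistic)
        res.n_removed = len(removed_r)
    return res


def _metric_fn(metric: str) -> Callable[[np.ndarray, np.ndarray], float]:
    if metric == "pearson":
        return lambda p, o: float(stats.pearsonr(p, o).statistic)
    if metric == "spearman":
        return lambda p, o: float(stats.spearmanr(p, o).statistic)
    raise ValueError(f"unknown metric {metric!r}")


def remove_outliers(
    pred: Sequence[float],
    obs: Sequence[float],
    frac: float,
    metric: str = "pearson",
) -> list[int]:
    """Greedy outlier removal: floor(frac * n) points, each step removing
    the point whose removal most improves the metric (ties: lowest index).
    Returns the removed indices in removal order.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if not 0 <= frac < 1:
        raise ValueError("frac must be in [0, 1)")
    fn = _metric_fn(metric)
    n_remove = int(np.floor(frac * len(pred)))
    active = list(range(len(pred)))
    removed: list[int] = []
    for _ in range(n_remove):
        best_idx, best_val = None, -np.inf
        for idx in active:
            rest = [k for k in active if k != idx]
            val = fn(pred[rest], obs[rest])
            if val > best_val + 1e-15:
                best_idx, best_val = idx, val
        active.remove(best_idx)
        removed.append(best_idx)
    return removed


@dataclass
class HillFit:
    """Constrained Hill-curve fit y = a x^n / (x^n + K^n), a <= 1."""

    a: float
    n: float
    K: float
    sse: float
    degenerate: bool = False

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.a * x**self.n / (x**self.n + self.K**self.n)


def _hill(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, n, k = np.abs(params)
    a = min(a, 1.0)
    n = min(n, 50.0)  # keep x**n finite during restarts
    with np.errstate(over="ignore"):
        xn = x ** n
        return a * xn / (xn + min(k, 1e6) ** n)


def hill_fit(
    x: Sequence[float],
    y: Sequence[float],
    n_restarts: int = 100,
    seed: int = 0,
) -> HillFit:
    """Least-squares Hill fit with the reparameterized constraints
    (non-negative parameters via absolute values, plateau clamped at 1);
    best of ``n_restarts`` random starts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 matching points")
    if np.ptp(y) == 0:
        return HillFit(a=float(y[0]), n=0.0, K=0.0, sse=0.0, degenerate=True)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        p0 = np.array(
            [rng.uniform(0.1, 1.5), rng.uniform(0.2, 5.0), rng.uniform(0.05, 2.0)]
        )
        try:
            res = least_squares(lambda p: _hill(p, x) - y, p0, method="lm", max_nfev=2000)
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res.x)
    sse, p = best
    a, n, k = np.abs(p)
    return HillFit(a=float(min(a, 1.0)), n=float(n), K=float(k), sse=sse)


@dataclass
class SubsampleSummary:
    fraction: float
    mean: dict[str, float]
    sd: dict[str, float]
    results: list[BenchmarkResult]


def subsample_harness(
    db,
    run: Callable,
    fractions: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    repeats: int = 3,
    seed: int = 0,
    outlier_frac: float | None = None,
) -> list[SubsampleSummary]:
    """Re-run a prediction protocol on random chain subsamples of the
    structure database.

    ``run(db_subset)`` must return (pred, obs) vectors; the full protocol
    behind it (including re-deriving the contact potential from the
    subset) is the caller's. Fraction 1.0 uses the whole database
    unshuffled, so it reproduces the unsubsampled run exactly.
    """
    rng = np.random.default_rng(seed)
    out = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must be in (0, 1]")
        results = []
        for _ in range(repeats):
            sub = db if frac == 1.0 else db.subsample(frac, rng)
            pred, obs = run(sub)
            results.append(benchmark(pred, obs, outlier_frac=outlier_frac))
        keys = ("R", "rho", "rmse", "accuracy")
        mean = {k: float(np.mean([getattr(r, k) for r in results])) for k in keys}
        sd = {k: float(np.std([getattr(r, k) for r in results])) for k in keys}
        out.append(SubsampleSummary(frac, mean, sd, results))
    return out
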