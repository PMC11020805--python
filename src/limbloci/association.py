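"""Linear association between laterality (AveLI) and motor function (FMA).

Ordinary least squares of FMA on AveLI, with significance from a permutation
test on R^2 (y permuted against x; add-one correction, or exhaustive
enumeration for tiny n) and a pointwise confidence band for the fitted line
from case-resampling bootstrap percentiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations as _perms

import numpy as np

__all__ = [
    "fit_line",
    "permutation_p",
    "bootstrap_band",
    "Band",
    "RegressionResult",
    "associate",
]


def _validated(x, y, min_n: int):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression is degenerate")
    return x, y


def fit_line(x, y) -> tuple[float, float, float]:
    """OLS slope, intercept and R^2 (squared Pearson correlation)."""
    x, y = _validated(x, y, 3)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r2 = 0.0 if syy == 0 else sxy**2 / (sxx * syy)
    return slope, intercept, float(r2)


def _r2_perm(x: np.ndarray, y_perm: np.ndarray) -> np.ndarray:
    """R^2 of y-rows against fixed x, vectorised over permutations."""
    xc = x - x.mean()
    yc = y_perm - y_perm.mean(axis=1, keepdims=True)
    sxy = yc @ xc
    sxx = float(xc @ xc)
    syy = (yc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = sxy**2 / (sxx * syy)
    return np.where(syy == 0, 0.0, r2)


def permutation_p(x, y, n_perm: int = 10000, seed: int = 0, exact: bool | None = None) -> float:
    """Permutation p-value for the regression, statistic R^2.

    Samples ``n_perm`` permutations of y with the add-one correction
    p = (1 + #{R^2_perm >= R^2_obs}) / (n_perm + 1).  With ``exact=True`` (or
    automatically when n! <= n_perm) all n! permutations are enumerated and
    p = #{>=} / n!.
    """
    x, y = _validated(x, y, 3)
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    _, _, r2_obs = fit_line(x, y)
    n = len(x)
    n_total = math.factorial(n)
    if exact is None:
        exact = n_total <= n_perm
    if exact:
        y_perm = np.array([np.take(y, p) for p in _perms(range(n))])
        r2 = _r2_perm(x, y_perm)
        return float((r2 >= r2_obs - 1e-12).sum() / n_total)
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    r2 = _r2_perm(x, y[idx])
    return float((1 + (r2 >= r2_obs - 1e-12).sum()) / (n_perm + 1))


@dataclass
class Band:
    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_boot: int
    n_skipped: int

    def contains(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return (values >= self.lower) & (values <= self.upper)


def bootstrap_band(
    x,
    y,
    n_boot: int = 10000,
    level: float = 0.95,
    grid=None,
    seed: int = 0,
) -> Band:
    """Pointwise percentile band for the OLS line from case resampling.

    Draws with constant x (no refittable line) are skipped and counted; more
    than 10% skipped raises a warning.  The default evaluation grid is the
    observed x values (sorted).
    """
    x, y = _validated(x, y, 4)
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    grid = np.sort(x) if grid is None else np.asarray(grid, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xs = x[idx]
    ys = y[idx]
    xm = xs.mean(axis=1, keepdims=True)
    sxx = ((xs - xm) ** 2).sum(axis=1)
    ok = sxx > 0
    n_skipped = int((~ok).sum())
    if n_skipped > 0.10 * n_boot:
        warnings.warn(
            f"{n_skipped}/{n_boot} bootstrap draws had a constant predictor",
            stacklevel=2,
        )
    xs, ys, xm = xs[ok], ys[ok], xm[ok]
    sxx = sxx[ok]
    slope = ((xs - xm) * (ys - ys.mean(axis=1, keepdims=True))).sum(axis=1) / sxx
    intercept = ys.mean(axis=1) - slope * xm[:, 0]
    lines = intercept[:, None] + slope[:, None] * grid[None, :]
    q = (1.0 - level) / 2.0
    return Band(
        grid=grid,
        lower=np.quantile(lines, q, axis=0),
        upper=np.quantile(lines, 1.0 - q, axis=0),
        level=level,
        n_boot=n_boot,
        n_skipped=n_skipped,
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_perm: float
    band: Band
    n: int


def associate(
    x, y, n_perm: int = 10000, n_boot: int = 10000, level: float = 0.95, seed: int = 0
) -> RegressionResult:
    """Fit, permutation p and bootstrap band in one call."""
    slope, intercept, r2 = fit_line(x, y)
    p = permutation_p(x, y, n_perm=n_perm, seed=seed)
    band = bootstrap_band(x, y, n_boot=n_boot, level=level, seed=seed + 1)
    return RegressionResult(
        slope=slope, intercept=intercept, r2=r2, p_perm=p, band=band, n=len(np.ravel(x))
    )
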