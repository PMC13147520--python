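"""Two-regime modelling of a tissue response against membrane affinity.

The vasodilation endpoint rises nearly linearly with membrane affinity up
to a breakpoint and declines beyond it.  This module fits and compares
three ordinary-least-squares models of a response ``y`` on a single
descriptor ``x``:

* :class:`LinearTrend`      — ``y = b0 + b1 x``
* :class:`QuadraticTrend`   — ``y = b0 + b1 x + b2 x^2``
* :class:`SegmentedModel`   — ``y = b0 + b1 x + b2 (x - psi)_+``, a hinge
  continuous at the breakpoint ``psi``, with ``psi`` estimated by an
  exhaustive profile search over a grid (coarse pass over the 1st-99th
  percentile range in ``range/400`` steps, then local refinement on an
  exact 0.01-resolution grid).  The search is deterministic and global
  over the grid; ties in RSS resolve to the smallest candidate.

Model classes follow the model/results idiom: construct from data, call
``fit()``, and read estimates, fit statistics and ``summary()`` off the
returned results object.

Conventions (stated because only differences between models matter):

* AIC uses the Gaussian maximum-likelihood form
  ``n ln(2 pi rss/n) + n + 2 (k+1)`` and BIC ``... + ln(n) (k+1)``, with
  the error variance counted as a parameter alongside the ``k`` mean
  parameters (the convention of the R ``AIC()`` generic, so rankings are
  comparable to analyses done there).
* The segmented model counts the breakpoint as an estimated parameter
  (``k = 4``) in adjusted R^2 / AIC / BIC; the 3-parameter alternative is
  also exposed as ``r2_adj_fixed_psi`` since conventions differ between
  packages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("x and y must be complete (drop missing pairs first)")
    return x, y


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("degenerate design matrix (collinear or constant x)")
    resid = y - X @ beta
    return beta, float(resid @ resid)


def gaussian_aic(rss: float, n: int, k: int) -> float:
    """Gaussian ML AIC with k mean parameters (+1 for the error variance)."""
    return n * math.log(2.0 * math.pi * rss / n) + n + 2.0 * (k + 1)


def gaussian_bic(rss: float, n: int, k: int) -> float:
    return n * math.log(2.0 * math.pi * rss / n) + n + math.log(n) * (k + 1)


@dataclass
class RegressionFit:
    """OLS fit statistics for one candidate model.

    ``n_params`` counts every estimated mean parameter, including the
    breakpoint for the segmented model.  ``rse`` is the residual standard
    error ``sqrt(rss / (n - n_params))``.
    """

    name: str
    coefficients: np.ndarray
    n: int
    n_params: int
    rss: float
    r2: float
    r2_adj: float
    aic: float
    bic: float
    rse: float
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    design: np.ndarray = field(repr=False)
    fittedvalues: np.ndarray = field(repr=False)

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.fittedvalues

    def summary(self) -> str:
        lines = [
            f"{self.name} model  (n={self.n}, k={self.n_params})",
            "  coefficients: "
            + ", ".join(f"{b:.4g}" for b in self.coefficients),
            f"  RSS={self.rss:.4g}  R2={self.r2:.4f}  R2_adj={self.r2_adj:.4f}",
            f"  AIC={self.aic:.2f}  BIC={self.bic:.2f}  RSE={self.rse:.4g}",
        ]
        return "\n".join(lines)


@dataclass
class SegmentedFit(RegressionFit):
    """Segmented (hinge) fit: ``y = b0 + b1 x + b2 (x - psi)_+``."""

    psi: float = float("nan")
    r2_adj_fixed_psi: float = float("nan")  # 3-parameter convention

    @property
    def beta0(self) -> float:
        return float(self.coefficients[0])

    @property
    def beta1(self) -> float:
        """Slope of the low regime."""
        return float(self.coefficients[1])

    @property
    def beta2(self) -> float:
        """Change in slope at the breakpoint."""
        return float(self.coefficients[2])

    @property
    def right_slope(self) -> float:
        return self.beta1 + self.beta2

    def summary(self) -> str:
        return (
            super().summary()
            + f"\n  breakpoint psi={self.psi:.2f}  left slope={self.beta1:.3f}"
            f"  right slope={self.right_slope:.3f}"
            f"  (R2_adj at fixed psi: {self.r2_adj_fixed_psi:.4f})"
        )


def _finish(name, x, y, X, beta, rss, k, extra_cls=RegressionFit, **extra) -> RegressionFit:
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k) if n > k else float("nan")
    rse = math.sqrt(rss / (n - k)) if n > k else float("nan")
    return extra_cls(
        name=name, coefficients=beta, n=n, n_params=k, rss=rss, r2=r2,
        r2_adj=r2_adj, aic=gaussian_aic(rss, n, k), bic=gaussian_bic(rss, n, k),
        rse=rse, x=x, y=y, design=X, fittedvalues=X @ beta, **extra,
    )


class LinearTrend:
    """OLS line of a response on one descriptor."""

    min_n = 3

    def __init__(self, y: Sequence[float], x: Sequence[float]):
        self.x, self.y = _as_xy(x, y)
        if len(self.x) < self.min_n:
            raise ValueError(f"need n >= {self.min_n}, got {len(self.x)}")

    def _design(self) -> np.ndarray:
        return np.column_stack([np.ones_like(self.x), self.x])

    def fit(self) -> RegressionFit:
        X = self._design()
        beta, rss = _ols(X, self.y)
        return _finish("linear", self.x, self.y, X, beta, rss, k=X.shape[1])


class QuadraticTrend(LinearTrend):
    """OLS parabola of a response on one descriptor."""

    min_n = 4

    def _design(self) -> np.ndarray:
        return np.column_stack([np.ones_like(self.x), self.x, self.x**2])

    def fit(self) -> RegressionFit:
        X = self._design()
        beta, rss = _ols(X, self.y)
        return _finish("quadratic", self.x, self.y, X, beta, rss, k=X.shape[1])


@dataclass(frozen=True)
class GridSearch:
    """Profile-search specification for the breakpoint."""

    coarse_steps: int = 400
    refine_resolution: float = 0.01
    lower_pct: float = 1.0
    upper_pct: float = 99.0


class SegmentedModel:
    """Continuous one-breakpoint (hinge) regression with profiled psi.

    A candidate breakpoint is admissible when at least two distinct x
    values lie strictly on each side, so both regime slopes are
    identified.  ``fit`` profiles the breakpoint: for each candidate psi
    the remaining parameters are the OLS solution on
    ``(1, x, (x - psi)_+)`` and the candidate minimising RSS wins.
    """

    min_n = 6

    def __init__(self, y: Sequence[float], x: Sequence[float]):
        self.x, self.y = _as_xy(x, y)
        if len(self.x) < self.min_n:
            raise ValueError(f"need n >= {self.min_n}, got {len(self.x)}")

    def _admissible(self, psi: np.ndarray) -> np.ndarray:
        xs = np.unique(self.x)
        below = (xs[None, :] < psi[:, None]).sum(axis=1)
        above = (xs[None, :] > psi[:, None]).sum(axis=1)
        return (below >= 2) & (above >= 2)

    def _rss_at(self, psi: float) -> tuple[np.ndarray, float, np.ndarray]:
        X = np.column_stack(
            [np.ones_like(self.x), self.x, np.maximum(self.x - psi, 0.0)]
        )
        beta, rss = _ols(X, self.y)
        return beta, rss, X

    def profile_rss(self, candidates: Sequence[float]) -> pd.Series:
        """RSS profile over admissible candidate breakpoints."""
        cand = np.asarray(candidates, dtype=float)
        cand = cand[self._admissible(cand)]
        return pd.Series([self._rss_at(p)[1] for p in cand], index=cand, name="rss")

    def fit(self, search: GridSearch = GridSearch()) -> SegmentedFit:
        lo, hi = np.percentile(self.x, [search.lower_pct, search.upper_pct])
        if not lo < hi:
            raise ValueError("degenerate x range for breakpoint search")
        step = (hi - lo) / search.coarse_steps
        coarse = np.arange(lo, hi + step / 2, step)
        profile = self.profile_rss(coarse)
        if profile.empty:
            raise ValueError("no admissible breakpoint candidate")
        best = float(profile.idxmin())
        best_rss = float(profile.min())
        # refine on an exact multiple-of-resolution grid spanning one
        # coarse step either side of the coarse optimum
        res = search.refine_resolution
        fine = np.round(
            np.arange(best - step, best + step + res / 2, res) / res
        ) * res
        fine_profile = self.profile_rss(np.unique(fine))
        psi = best
        if not fine_profile.empty and fine_profile.min() <= best_rss:
            psi, best_rss = float(fine_profile.idxmin()), float(fine_profile.min())
        # boundary polish: the RSS profile is continuous but can fall
        # steeply toward the admissibility boundary just beside a data
        # point, where a fixed-resolution grid cannot land; probe the
        # data-adjacent candidates around the current optimum
        xs = np.unique(self.x)
        near = xs[np.abs(xs - psi) <= max(step, res) + 1e-12]
        eps = 1e-6 * max(1.0, float(np.ptp(self.x)))
        polish = np.concatenate([near - eps, near, near + eps])
        polish_profile = self.profile_rss(polish)
        if not polish_profile.empty and polish_profile.min() < best_rss:
            psi = float(polish_profile.idxmin())
        beta, rss, X = self._rss_at(psi)
        n = len(self.x)
        tss = float(((self.y - self.y.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
        fit = _finish(
            "segmented", self.x, self.y, X, beta, rss, k=4,
            extra_cls=SegmentedFit, psi=psi,
            r2_adj_fixed_psi=1.0 - (1.0 - r2) * (n - 1) / (n - 3),
        )
        return fit


# -- functional surface -----------------------------------------------------

def fit_linear(x, y) -> RegressionFit:
    return LinearTrend(y, x).fit()


def fit_quadratic(x, y) -> RegressionFit:
    return QuadraticTrend(y, x).fit()


def fit_segmented(x, y, search: GridSearch = GridSearch()) -> SegmentedFit:
    return SegmentedModel(y, x).fit(search)


@dataclass
class ModelComparison:
    """Side-by-side fit statistics plus the linear-vs-quadratic F-test."""

    table: pd.DataFrame
    f_test: dict
    best_by_aic: str

    def to_dict(self) -> dict:
        models = {}
        for name, row in self.table.iterrows():
            models[name] = {
                k: (v if isinstance(v, (int, str)) else float(v))
                for k, v in row.items()
                if not (isinstance(v, float) and math.isnan(v))
            }
        return {"models": models, "f_test": self.f_test, "best_by_aic": self.best_by_aic}


def ftest_nested(small: RegressionFit, big: RegressionFit) -> dict:
    """F-test of a nested pair of OLS fits on the same data.

    ``F = ((rss1 - rss2) / (df1 - df2)) / (rss2 / df2)`` with residual
    degrees of freedom ``df = n - k``.  Identical fits give F = 0, p = 1.
    """
    if small.n != big.n or not np.array_equal(small.y, big.y):
        raise ValueError("F-test requires fits on identical data")
    df1, df2 = small.n - small.n_params, big.n - big.n_params
    if df2 <= 0 or df1 < df2:
        raise ValueError("models are not properly nested")
    if df1 == df2:
        if math.isclose(small.rss, big.rss, rel_tol=1e-12, abs_tol=1e-12):
            return {"F": 0.0, "df1": 0, "df2": int(df2), "p": 1.0}
        raise ValueError("models have equal df but different RSS; not nested")
    F = ((small.rss - big.rss) / (df1 - df2)) / (big.rss / df2)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df1 - df2, df2)) if F > 0 else 1.0
    return {"F": float(F), "df1": int(df1 - df2), "df2": int(df2), "p": p}


def compare_models(fits: Sequence[RegressionFit]) -> ModelComparison:
    """Compare fits of the same (x, y) by adjusted R^2 / AIC / BIC / RSE.

    The quadratic model, when present, is additionally tested against the
    linear model by the nested F-test.  The best model is flagged by AIC.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        if f.n != ref.n or not (np.array_equal(f.x, ref.x) and np.array_equal(f.y, ref.y)):
            raise ValueError("all fits must be on identical (x, y)")
    rows = {}
    for f in fits:
        row = {
            "k": f.n_params, "rss": f.rss, "r2": f.r2, "r2_adj": f.r2_adj,
            "aic": f.aic, "bic": f.bic, "rse": f.rse,
        }
        if isinstance(f, SegmentedFit):
            row["psi"] = f.psi
            row["r2_adj_fixed_psi"] = f.r2_adj_fixed_psi
        rows[f.name] = row
    table = pd.DataFrame(rows).T
    by_name = {f.name: f for f in fits}
    f_test = {}
    if "linear" in by_name and "quadratic" in by_name:
        f_test = ftest_nested(by_name["linear"], by_name["quadratic"])
    best = min(fits, key=lambda f: f.aic).name
    return ModelComparison(table=table, f_test=f_test, best_by_aic=best)


@dataclass
class InfluenceReport:
    """Per-observation Cook's distance and leverage for an OLS fit."""

    frame: pd.DataFrame  # residual, leverage, cook_d, flagged
    threshold: float
    n_params: int

    @property
    def flagged(self) -> list:
        return list(self.frame.index[self.frame["flagged"]])


def cooks_distance(fit: RegressionFit, index: Sequence | None = None) -> InfluenceReport:
    """Cook's distance with the 4/n influence threshold.

    ``D_i = e_i^2 h_ii / (p s^2 (1 - h_ii)^2)`` with ``s^2 = rss/(n-p)``
    and p the number of design columns.  For the segmented model the
    hinge column is held fixed at the estimated breakpoint, so p = 3
    there.  Exact-leverage points (h = 1) get infinite distance and are
    flagged.
    """
    X = fit.design
    n, p = X.shape
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    h = np.clip(np.diag(H), 0.0, 1.0)
    e = fit.residuals
    s2 = fit.rss / (n - p)
    with np.errstate(divide="ignore"):
        d = e**2 * h / (p * s2 * (1.0 - h) ** 2)
    d = np.where(np.isclose(h, 1.0), np.inf, d)
    threshold = 4.0 / n
    frame = pd.DataFrame(
        {
            "residual": e,
            "leverage": h,
            "cook_d": d,
            "flagged": (d > threshold) | np.isclose(h, 1.0),
        },
        index=index if index is not None else pd.RangeIndex(n),
    )
    return InfluenceReport(frame=frame, threshold=threshold, n_params=p)


def split_regimes(
    x: pd.Series, rule: float | Sequence[str]
) -> tuple[list, list]:
    """Partition compounds into low/high membrane-affinity regimes.

    ``rule`` is either a numeric threshold on ``x`` (low: x <= rule) or an
    explicit list of compound ids forming the high side.  An empty side
    raises a warning, not an error.
    """
    import warnings

    x = x.dropna()
    if isinstance(rule, (int, float)) and not isinstance(rule, bool):
        low = list(x.index[x <= rule])
        high = list(x.index[x > rule])
    else:
        high_set = set(rule)
        low = [c for c in x.index if c not in high_set]
        high = [c for c in x.index if c in high_set]
    if not low or not high:
        warnings.warn("one regime side is empty", UserWarning, stacklevel=2)
    return low, high
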