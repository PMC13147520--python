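"""Chromatographic lipophilicity indices from raw retention data.

Two experimental modes are covered:

* **Gradient CHI** — the chromatographic hydrophobicity index is obtained
  by linearly mapping gradient retention times onto a reference CHI scale
  defined by a calibration-standards mixture: an ordinary least-squares
  line ``chi_ref = slope * t_r + intercept`` is fitted to the standards
  and then applied to analyte retention times.  The same procedure serves
  the C18 and phosphatidylcholine-IAM phases; only the standards file and
  column differ.

* **Isocratic log k** — on the sphingomyelin phase the retention factor
  ``k = (t_R - t_0) / t_0`` is computed from the replicate-mean retention
  time and the column dead time ``t_0``, and reported as ``log10 k``.

Replicates are aggregated by arithmetic mean; a replicate relative spread
above 3 % of the mean is flagged with a warning (it mirrors the usual
triplicate acceptance rule) but does not abort the computation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: Relative replicate spread above which a warning is emitted.
REPLICATE_SPREAD_TOL = 0.03


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration compound: gradient retention time and reference CHI."""

    name: str
    t_r: float  # min
    chi_ref: float  # dimensionless CHI scale

    def __post_init__(self) -> None:
        if not self.t_r > 0:
            raise ValueError(f"standard {self.name!r}: t_r must be > 0")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted CHI-vs-retention-time line for one gradient mode."""

    slope: float  # CHI per min
    intercept: float  # CHI
    r_squared: float
    n_standards: int
    t_r_min: float  # standards' retention-time range
    t_r_max: float

    def in_range(self, t_r: float) -> bool:
        return self.t_r_min <= t_r <= self.t_r_max

    def predict(self, t_r: float) -> float:
        return self.slope * t_r + self.intercept


class ExtrapolationWarning(UserWarning):
    """Retention time outside the calibration standards' range."""


class ReplicateSpreadWarning(UserWarning):
    """Replicate retention times spread more than the 3 % tolerance."""


@dataclass(frozen=True)
class IsocraticRun:
    """Replicate isocratic retention times plus column dead time (min)."""

    t_r_replicates: tuple[float, ...]
    t_0: float

    def __post_init__(self) -> None:
        if not self.t_0 > 0:
            raise ValueError("dead time t_0 must be > 0")
        if not self.t_r_replicates:
            raise ValueError("at least one replicate retention time required")

    @property
    def mean_t_r(self) -> float:
        return float(np.mean(self.t_r_replicates))

    @property
    def relative_spread(self) -> float:
        reps = np.asarray(self.t_r_replicates, dtype=float)
        if len(reps) == 1:
            return 0.0
        return float((reps.max() - reps.min()) / reps.mean())


def fit_chi_calibration(standards: Sequence[CalibrationStandard]) -> CalibrationModel:
    """OLS calibration line ``chi_ref = slope * t_r + intercept``.

    Requires at least three standards with non-degenerate retention times.
    ``r_squared`` is the squared Pearson correlation of the same fit.
    """
    if len(standards) < 3:
        raise ValueError(f"need >= 3 calibration standards, got {len(standards)}")
    t_r = np.array([s.t_r for s in standards], dtype=float)
    chi = np.array([s.chi_ref for s in standards], dtype=float)
    if np.ptp(t_r) == 0:
        raise ValueError("calibration standards have zero retention-time variance")
    res = stats.linregress(t_r, chi)
    model = CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_standards=len(standards),
        t_r_min=float(t_r.min()),
        t_r_max=float(t_r.max()),
    )
    log.info(
        "CHI calibration: slope=%.4f intercept=%.4f R2=%.4f n=%d",
        model.slope, model.intercept, model.r_squared, model.n_standards,
    )
    return model


def chi_from_retention(
    t_r: float, model: CalibrationModel, *, extrapolate: bool = False
) -> float:
    """Map a gradient retention time to the CHI scale.

    Outside the standards' range a :class:`ExtrapolationWarning` is emitted
    unless ``extrapolate=True`` was passed explicitly.
    """
    if not model.in_range(t_r) and not extrapolate:
        warnings.warn(
            f"t_r={t_r:g} min outside calibration range "
            f"[{model.t_r_min:g}, {model.t_r_max:g}]; CHI value is extrapolated",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return model.predict(t_r)


def logk_isocratic(run: IsocraticRun) -> float:
    """log10 retention factor of an isocratic run.

    ``k = (mean t_R - t_0) / t_0``; the replicate spread check is applied
    first.  A mean retention time at or below the dead time is a hard
    error (the compound did not measurably retain, or t_0 is wrong).
    """
    if run.relative_spread > REPLICATE_SPREAD_TOL:
        warnings.warn(
            f"replicate spread {run.relative_spread:.1%} exceeds "
            f"{REPLICATE_SPREAD_TOL:.0%} tolerance",
            ReplicateSpreadWarning,
            stacklevel=2,
        )
    t_r = run.mean_t_r
    if t_r <= run.t_0:
        raise ValueError(f"mean t_r ({t_r:g}) must exceed dead time t_0 ({run.t_0:g})")
    return math.log10((t_r - run.t_0) / run.t_0)


# ---------------------------------------------------------------------------
# CSV plumbing for the CLI

def read_standards(path: str | Path) -> list[CalibrationStandard]:
    """Read a ``name,t_r_min,chi_ref`` standards CSV."""
    df = pd.read_csv(path)
    return [
        CalibrationStandard(str(r["name"]), float(r["t_r_min"]), float(r["chi_ref"]))
        for _, r in df.iterrows()
    ]


def index_measurements(
    runs: pd.DataFrame,
    model: CalibrationModel | None = None,
    *,
    extrapolate: bool = False,
) -> pd.DataFrame:
    """Compute indices for a measurements frame (``runs.csv`` schema).

    Columns: ``compound_id, t_r_min_rep1..rep3, t0_min, mode`` with mode in
    {gradient_iam, gradient_c18, isocratic_sph}.  Gradient rows need a
    fitted ``model``; isocratic rows use ``t0_min``.  Returns a frame with
    ``compound_id, mode, value, flagged`` where ``flagged`` marks gradient
    extrapolations or excessive replicate spread.
    """
    rep_cols = [c for c in runs.columns if c.startswith("t_r_min_rep")]
    rows = []
    for _, r in runs.iterrows():
        reps = tuple(float(r[c]) for c in rep_cols if pd.notna(r[c]))
        mode = str(r["mode"])
        flagged = False
        if mode.startswith("gradient"):
            if model is None:
                raise ValueError("gradient measurements require a calibration model")
            t_r = float(np.mean(reps))
            spread = (max(reps) - min(reps)) / t_r if len(reps) > 1 else 0.0
            if spread > REPLICATE_SPREAD_TOL:
                warnings.warn(
                    f"{r['compound_id']}: replicate spread {spread:.1%} > 3%",
                    ReplicateSpreadWarning,
                    stacklevel=2,
                )
                flagged = True
            if not model.in_range(t_r) and not extrapolate:
                flagged = True
            value = chi_from_retention(t_r, model, extrapolate=extrapolate)
        elif mode == "isocratic_sph":
            run = IsocraticRun(reps, float(r["t0_min"]))
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                value = logk_isocratic(run)
            flagged = any(issubclass(w.category, ReplicateSpreadWarning) for w in caught)
        else:
            raise ValueError(f"unknown measurement mode {mode!r}")
        rows.append({"compound_id": r["compound_id"], "mode": mode,
                     "value": value, "flagged": flagged})
    return pd.DataFrame(rows, columns=["compound_id", "mode", "value", "flagged"])
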