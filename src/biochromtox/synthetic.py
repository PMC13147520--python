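"""Synthetic compound panels with the statistical structure of the assay.

The generator emulates a small lipophilicity-driven toxicity panel:

* nine descriptor columns driven by one latent lipophilicity factor with
  a configurable inter-descriptor correlation, scaled per column family
  (gradient CHI on the membrane phase, CHI on C18, isocratic log k, and
  log P / log D style columns);
* cytotoxic potency linear in the membrane-affinity index on the pIC50
  scale, ``pIC50 = a + b * chi_iam + eps``, with right-censoring flagged
  wherever the implied IC50 exceeds the assay ceiling;
* a tissue response (vasodilation %) piecewise linear in the same index
  with a breakpoint — a rise-then-fall, clipped to [0, 100];
* missing cells injected completely at random at a configured rate.

A single seeded generator stream drives everything, so identical
configurations reproduce byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import (
    DESCRIPTOR_COLUMNS,
    ENDPOINT_COLUMNS,
    POTENCY_COLUMNS,
    DescriptorTable,
    EndpointTable,
)
from .chromatography import CalibrationStandard
from .potency import CENSOR_THRESHOLD_UM, pic50_from_uM

#: Per-column (offset, scale) mapping from the standardised latent
#: lipophilicity axis to each descriptor family's natural range.
_COLUMN_SCALES = {
    "acd_logp_classic": (4.0, 1.3),
    "consensus_logp_acd": (4.0, 1.2),
    "acd_logp_galas": (4.0, 1.1),
    "acd_logd": (4.0, 1.2),
    "logp_chemicalize": (4.7, 1.4),
    "logd_chemicalize": (4.6, 1.4),
    "chi_c18": (83.0, 18.0),
    "logk_iam_sph": (1.0, 0.5),
}


@dataclass(frozen=True)
class DescriptorModel:
    mean: float = 44.0  # chi_iam location
    sd: float = 7.0  # chi_iam spread
    rho_d: float = 0.85  # inter-descriptor correlation


@dataclass(frozen=True)
class PotencyModel:
    intercept: float = 0.5  # a, pIC50 at chi_iam = 0
    slope: float = 0.07  # b, pIC50 per chi_iam unit
    noise_sd: float = 0.25  # sigma_p, pIC50 units
    censor_threshold_uM: float = CENSOR_THRESHOLD_UM


@dataclass(frozen=True)
class RegimeModel:
    psi_true: float = 47.0  # breakpoint on the chi_iam axis
    s1: float = 3.3  # low-regime slope, % per chi_iam unit
    s2: float = -8.0  # high-regime slope
    noise_sd: float = 6.0  # sigma_v, percentage points
    level_at_psi: float = 80.0  # response height at the breakpoint


@dataclass(frozen=True)
class SyntheticConfig:
    n_compounds: int = 18
    seed: int = 0
    descriptor_model: DescriptorModel = field(default_factory=DescriptorModel)
    potency_model: PotencyModel = field(default_factory=PotencyModel)
    regime_model: RegimeModel = field(default_factory=RegimeModel)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_compounds < 6:
            raise ValueError("n_compounds must be >= 6")
        if self.potency_model.noise_sd < 0 or self.regime_model.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not self.potency_model.censor_threshold_uM > 0:
            raise ValueError("censor_threshold_uM must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def censoring_probability(config: SyntheticConfig) -> float:
    """Analytic censoring fraction under the generating model.

    ``chi_iam`` is Gaussian and potency noise Gaussian, so marginally
    ``pIC50 ~ N(a + b*mean, b^2 sd^2 + sigma_p^2)``; a cell is censored
    when the implied IC50 exceeds the ceiling, i.e. when pIC50 falls
    below ``-log10(threshold * 1e-6)``.
    """
    d, p = config.descriptor_model, config.potency_model
    m = p.intercept + p.slope * d.mean
    s = math.sqrt((p.slope * d.sd) ** 2 + p.noise_sd**2)
    cut = pic50_from_uM(p.censor_threshold_uM)
    if s == 0:
        return float(m < cut)
    return float(stats.norm.cdf((cut - m) / s))


def generate_panel(
    config: SyntheticConfig,
) -> tuple[DescriptorTable, EndpointTable, dict]:
    """Generate one synthetic panel plus its ground-truth record.

    The breakpoint is guaranteed to fall strictly inside the generated
    ``chi_iam`` range (the extreme draws are nudged just past it when a
    draw leaves the breakpoint outside, preserving the configured spread
    elsewhere).
    """
    rng = np.random.default_rng(config.seed)
    d, p, g = config.descriptor_model, config.potency_model, config.regime_model
    n = config.n_compounds
    ids = [f"SYN{i:03d}" for i in range(1, n + 1)]

    # one-factor latent structure: corr(z_j, z_k) = rho_d
    factor = rng.normal(size=n)
    lam = math.sqrt(d.rho_d)
    resid = math.sqrt(1.0 - d.rho_d)
    latents = {
        col: lam * factor + resid * rng.normal(size=n)
        for col in DESCRIPTOR_COLUMNS
    }
    chi_iam = d.mean + d.sd * latents["chi_iam"]
    # keep the true breakpoint interior to the observed index range
    if chi_iam.min() >= g.psi_true:
        chi_iam[np.argmin(chi_iam)] = g.psi_true - d.sd
    if chi_iam.max() <= g.psi_true:
        chi_iam[np.argmax(chi_iam)] = g.psi_true + d.sd

    frame = pd.DataFrame(index=pd.Index(ids, name="compound_id"))
    frame["name"] = ids
    frame["cas"] = ""
    frame["smiles"] = ""
    frame["mw"] = np.round(200.0 + 40.0 * np.abs(latents["acd_logp_classic"]), 2)
    for col in DESCRIPTOR_COLUMNS:
        if col == "chi_iam":
            frame[col] = chi_iam
        else:
            off, scale = _COLUMN_SCALES[col]
            frame[col] = off + scale * latents[col]
    descriptors = DescriptorTable(frame)

    # potency: pIC50 linear in chi_iam, censored below the ceiling pIC50
    cut = pic50_from_uM(p.censor_threshold_uM)
    values = pd.DataFrame(np.nan, index=frame.index, columns=list(ENDPOINT_COLUMNS))
    censored = pd.DataFrame(False, index=frame.index, columns=list(POTENCY_COLUMNS))
    true_pic50 = {}
    for col in POTENCY_COLUMNS:
        pic50 = p.intercept + p.slope * chi_iam + rng.normal(0.0, p.noise_sd, size=n)
        true_pic50[col] = pic50.copy()
        cens = pic50 < cut
        censored[col] = cens
        values[col] = np.where(cens, cut, pic50)  # ceiling substitution, flagged

    # tissue response: continuous hinge in chi_iam, clipped to [0, 100]
    hinge = np.maximum(chi_iam - g.psi_true, 0.0)
    vaso_clean = g.level_at_psi + g.s1 * (chi_iam - g.psi_true) + (g.s2 - g.s1) * hinge
    vaso = vaso_clean + rng.normal(0.0, g.noise_sd, size=n)
    values["vasodilation_pct"] = np.clip(vaso, 0.0, 100.0)

    # organism endpoint: same linear potency structure, own noise draw
    pec50 = p.intercept + p.slope * chi_iam + rng.normal(0.0, p.noise_sd, size=n)
    values["pec50_daphnia"] = pec50

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.mask(mask)

    endpoints = EndpointTable(values, censored, scenario="ceiling")
    truth = {
        "config": config,
        "chi_iam": chi_iam,
        "true_pic50": true_pic50,
        "vasodilation_clean": vaso_clean,
        "psi_true": g.psi_true,
        "slope_true": p.slope,
        "censoring_probability": censoring_probability(config),
    }
    return descriptors, endpoints, truth


def generate_calibration_set(
    n_standards: int,
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int,
    t_r_range: tuple[float, float] = (0.5, 5.5),
) -> list[CalibrationStandard]:
    """Synthetic CHI calibration standards on a linear retention model.

    Retention times are equally spaced on ``t_r_range`` (minutes) and the
    reference CHI values are ``slope * t_r + intercept`` plus Gaussian
    noise.
    """
    if n_standards < 3:
        raise ValueError("need at least 3 standards")
    rng = np.random.default_rng(seed)
    t_r = np.linspace(*t_r_range, n_standards)
    chi = slope * t_r + intercept + rng.normal(0.0, noise_sd, size=n_standards)
    return [
        CalibrationStandard(f"STD{i:02d}", float(t), float(c))
        for i, (t, c) in enumerate(zip(t_r, chi), start=1)
    ]
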