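"""Potency transforms and right-censoring scenarios.

Cytotoxicity is analysed on the pIC50 scale, ``pIC50 = -log10(IC50 / M)``,
with IC50 arriving in micromolar.  Aquatic EC50 values arrive in mg L^-1
and are first converted to molar using the compound's molecular weight.

Values reported only as exceeding the assay ceiling (``IC50 > 100 uM``)
are right-censored.  Three substitution scenarios are supported:

* ``truncate100`` — substitute the conservative ceiling, 100 uM;
* ``truncate200`` — substitute an upper bound of 200 uM (the default, on
  which the reference analysis is based);
* ``exclude``     — drop censored values (they become missing).

All computation is full precision; rounding to two decimals happens only
at presentation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .tables import POTENCY_COLUMNS, EndpointTable, with_values

log = logging.getLogger(__name__)

#: Assay ceiling (uM) above which cytotoxicity values are right-censored.
CENSOR_THRESHOLD_UM = 100.0


class CensoringScenario(str, Enum):
    """How right-censored cytotoxicity values enter the analysis."""

    truncate100 = "truncate100"
    truncate200 = "truncate200"
    exclude = "exclude"

    @property
    def substitute_uM(self) -> float | None:
        return {"truncate100": 100.0, "truncate200": 200.0, "exclude": None}[self.value]


DEFAULT_SCENARIO = CensoringScenario.truncate200


@dataclass(frozen=True)
class RawToxicityValue:
    """A raw measurement with units and censor status."""

    value: float
    units: str  # 'uM' | 'mg_per_L' | 'percent'
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"raw toxicity value must be > 0, got {self.value}")
        if self.units not in ("uM", "mg_per_L", "percent"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.units == "percent" and self.censored:
            raise ValueError("percent values cannot be censored")


@dataclass(frozen=True)
class PotencyValue:
    """A transformed potency (pIC50/pEC50, -log10 molar)."""

    value: float
    scenario: str
    was_censored: bool


def pic50_from_uM(ic50_uM: float) -> float:
    return -math.log10(ic50_uM * 1e-6)


def ic50_to_pic50(
    raw: RawToxicityValue, scenario: CensoringScenario = DEFAULT_SCENARIO
) -> PotencyValue | None:
    """Transform a micromolar IC50 to pIC50 under a censoring scenario.

    Returns ``None`` (missing) for a censored value under ``exclude``.
    Feeding non-micromolar units is an error, never a silent
    miscomputation.
    """
    if raw.units != "uM":
        raise TypeError(f"ic50_to_pic50 requires uM input, got {raw.units!r}")
    scenario = CensoringScenario(scenario)
    if raw.censored:
        sub = scenario.substitute_uM
        if sub is None:
            return None
        return PotencyValue(pic50_from_uM(sub), scenario.value, True)
    return PotencyValue(pic50_from_uM(raw.value), scenario.value, False)


def ec50_to_pec50(raw: RawToxicityValue, mw: float | None) -> PotencyValue | None:
    """Transform an EC50 in mg L^-1 to pEC50 via molar conversion.

    ``pEC50 = -log10((value_mg_per_L / 1000) / mw)``.  A missing molecular
    weight yields missing with a logged reason rather than an error.
    """
    if raw.units != "mg_per_L":
        raise TypeError(f"ec50_to_pec50 requires mg_per_L input, got {raw.units!r}")
    if mw is None or (isinstance(mw, float) and math.isnan(mw)):
        log.warning("ec50_to_pec50: molecular weight missing, value dropped")
        return None
    if not mw > 0:
        raise ValueError(f"molecular weight must be > 0, got {mw}")
    molar = (raw.value / 1000.0) / mw
    return PotencyValue(-math.log10(molar), "none", raw.censored)


def apply_scenario(
    endpoints: EndpointTable, scenario: CensoringScenario = DEFAULT_SCENARIO
) -> EndpointTable:
    """Re-express censored cytotoxicity cells under a censoring scenario.

    Only the four pIC50 columns are touched, and within them only cells
    flagged censored: the stored value is replaced by the scenario's
    substitute (at full precision) or by missing under ``exclude``.
    Uncensored cells and the non-potency columns pass through unchanged.
    """
    scenario = CensoringScenario(scenario)
    values = endpoints.values.copy()
    n_sub = 0
    for col in POTENCY_COLUMNS:
        mask = endpoints.censored[col] & values[col].notna()
        if not mask.any():
            continue
        n_sub += int(mask.sum())
        if scenario.substitute_uM is None:
            values.loc[mask, col] = np.nan
        else:
            values.loc[mask, col] = pic50_from_uM(scenario.substitute_uM)
    if n_sub:
        log.warning(
            "censoring scenario %s applied to %d censored cells", scenario.value, n_sub
        )
    return with_values(endpoints, values, scenario.value)


def pivot_raw_endpoints(
    raw: pd.DataFrame,
    mw: pd.Series,
    scenario: CensoringScenario = DEFAULT_SCENARIO,
) -> EndpointTable:
    """Build a wide endpoint table from long raw measurements.

    ``raw`` follows the ``raw_endpoints.csv`` schema
    (``compound_id,endpoint,value,units,censored``); cytotoxicity rows are
    micromolar IC50s, the Daphnia rows are mg L^-1 EC50s (converted with
    ``mw``, indexed by compound_id), and vasodilation rows are percent.
    """
    from .tables import ENDPOINT_COLUMNS

    scenario = CensoringScenario(scenario)
    ids = list(dict.fromkeys(raw["compound_id"]))
    values = pd.DataFrame(np.nan, index=pd.Index(ids, name="compound_id"),
                          columns=list(ENDPOINT_COLUMNS))
    censored = pd.DataFrame(False, index=values.index, columns=list(POTENCY_COLUMNS))
    for _, r in raw.iterrows():
        cid, col = r["compound_id"], r["endpoint"]
        if col not in ENDPOINT_COLUMNS:
            raise ValueError(f"unknown endpoint {col!r}")
        rv = RawToxicityValue(float(r["value"]), str(r["units"]), bool(int(r["censored"])))
        if col in POTENCY_COLUMNS:
            pv = ic50_to_pic50(rv, scenario)
            censored.loc[cid, col] = rv.censored
            if pv is not None:
                values.loc[cid, col] = pv.value
        elif col == "pec50_daphnia":
            pv = ec50_to_pec50(rv, float(mw.get(cid, np.nan)))
            if pv is not None:
                values.loc[cid, col] = pv.value
        else:  # vasodilation_pct
            if rv.units != "percent":
                raise TypeError("vasodilation rows must be percent")
            values.loc[cid, col] = rv.value
    return EndpointTable(values, censored, scenario=scenario.value)
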