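"""Descriptor-endpoint correlation matrix with pairwise deletion.

Each cell of the matrix correlates one toxicity endpoint with one
lipophilicity descriptor over the compounds complete for that specific
pair (pairwise deletion), optionally restricted to a per-endpoint
compound subset.  Pearson r measures the linear association; Spearman
rho is computed as the Pearson coefficient of midranks (average ranks
for ties), which remains exact in the presence of tied potency values.
The two-sided p-value for r uses the exact t reference distribution,
``t = r * sqrt(n-2) / sqrt(1-r^2)`` with ``n-2`` degrees of freedom.

No multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import DESCRIPTOR_COLUMNS, ENDPOINT_COLUMNS, DescriptorTable, EndpointTable

log = logging.getLogger(__name__)

#: Minimum complete pairs for a reported coefficient.
MIN_PAIRS = 3


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment r on complete pairs; NaN if undefined.

    Fewer than three complete pairs, or zero variance in either variable,
    gives NaN (a missing cell) with the reason logged.
    """
    x, y = _clean_pairs(x, y)
    if len(x) < MIN_PAIRS:
        log.info("pearson: only %d complete pairs (< %d)", len(x), MIN_PAIRS)
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.info("pearson: zero variance, coefficient undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho: Pearson correlation of midranks (ties averaged)."""
    x, y = _clean_pairs(x, y)
    if len(x) < MIN_PAIRS:
        log.info("spearman: only %d complete pairs (< %d)", len(x), MIN_PAIRS)
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.info("spearman: zero variance, coefficient undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson coefficient at sample size n.

    Uses ``t = r sqrt(n-2) / sqrt(1-r^2)`` with ``n-2`` degrees of
    freedom.  ``|r| = 1`` is reported as p = 0 (the t statistic is
    unbounded there).
    """
    if n < MIN_PAIRS:
        raise ValueError(f"need n >= {MIN_PAIRS}, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        log.info("pearson_pvalue: |r| = 1, p reported as 0")
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class CorrelationCell:
    """One (endpoint, descriptor) cell of the correlation matrix."""

    endpoint: str
    descriptor: str
    n: int
    r: float
    rho: float
    p_r: float
    is_row_max: bool = False
    note: str = ""

    @property
    def missing(self) -> bool:
        return math.isnan(self.r)


@dataclass
class CorrelationMatrix:
    """Grid of correlation cells (endpoints x descriptors)."""

    cells: list[CorrelationCell]
    scenario: str = ""
    subset_tags: dict[str, str] = field(default_factory=dict)

    def cell(self, endpoint: str, descriptor: str) -> CorrelationCell:
        for c in self.cells:
            if c.endpoint == endpoint and c.descriptor == descriptor:
                return c
        raise KeyError((endpoint, descriptor))

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: ``endpoint,descriptor,n,r,rho,p_r,is_row_max``."""
        return pd.DataFrame(
            [
                {
                    "endpoint": c.endpoint,
                    "descriptor": c.descriptor,
                    "n": c.n,
                    "r": c.r,
                    "rho": c.rho,
                    "p_r": c.p_r,
                    "is_row_max": c.is_row_max,
                }
                for c in self.cells
            ]
        )

    def pivot(self, stat: str = "r") -> pd.DataFrame:
        """Wide endpoint-by-descriptor frame of one statistic."""
        return self.to_frame().pivot(index="endpoint", columns="descriptor", values=stat)


def exclusion_subsets(
    endpoints: EndpointTable, exclusions: Mapping[str, Iterable[str]]
) -> dict[str, list[str]]:
    """Turn per-endpoint exclusion lists into per-endpoint include lists."""
    subsets = {}
    for endpoint, excluded in exclusions.items():
        drop = set(excluded)
        subsets[endpoint] = [c for c in endpoints.compound_ids if c not in drop]
    return subsets


def build_matrix(
    descriptors: DescriptorTable,
    endpoints: EndpointTable,
    subsets: Mapping[str, Sequence[str]] | None = None,
) -> CorrelationMatrix:
    """Correlate every endpoint with every descriptor, pairwise-deleted.

    ``subsets`` optionally maps an endpoint to the compound ids to include
    for that endpoint's whole row (e.g. the low-to-moderate membrane
    affinity subset for vasodilation).  Cells with fewer than three
    complete pairs are missing.  The largest ``|r|`` of each endpoint row
    is flagged ``is_row_max`` (all cells sharing the rounded 2-dp maximum
    are flagged, mirroring how ties are highlighted in a printed table).
    """
    subsets = dict(subsets or {})
    desc = descriptors.descriptors
    common = [c for c in endpoints.compound_ids if c in desc.index]
    if not common:
        raise ValueError("descriptor and endpoint tables share no compound_id")
    cells: list[CorrelationCell] = []
    subset_tags: dict[str, str] = {}
    for endpoint in ENDPOINT_COLUMNS:
        row: list[CorrelationCell] = []
        include = [c for c in common if c in set(subsets.get(endpoint, common))]
        subset_tags[endpoint] = (
            f"subset n<={len(include)}" if endpoint in subsets else "all"
        )
        y_full = endpoints.values.loc[include, endpoint]
        for descriptor in DESCRIPTOR_COLUMNS:
            x_full = desc.loc[include, descriptor]
            keep = x_full.notna() & y_full.notna()
            n = int(keep.sum())
            dropped = [c for c in include if not keep.loc[c]]
            if dropped:
                log.info(
                    "cell (%s, %s): pairwise deletion removed %s",
                    endpoint, descriptor, dropped,
                )
            if n < MIN_PAIRS:
                row.append(
                    CorrelationCell(endpoint, descriptor, n,
                                    float("nan"), float("nan"), float("nan"),
                                    note=f"n={n} < {MIN_PAIRS}")
                )
                continue
            x = x_full[keep].to_numpy()
            y = y_full[keep].to_numpy()
            r = pearson(x, y)
            rho = spearman(x, y)
            p = pearson_pvalue(r, n) if not math.isnan(r) else float("nan")
            row.append(CorrelationCell(endpoint, descriptor, n, r, rho, p))
        finite = [c for c in row if not c.missing]
        if finite:
            best = max(abs(c.r) for c in finite)
            row = [
                CorrelationCell(
                    c.endpoint, c.descriptor, c.n, c.r, c.rho, c.p_r,
                    is_row_max=(not c.missing and round(abs(c.r), 2) == round(best, 2)),
                    note=c.note,
                )
                for c in row
            ]
        cells.extend(row)
    return CorrelationMatrix(cells, scenario=endpoints.scenario, subset_tags=subset_tags)
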