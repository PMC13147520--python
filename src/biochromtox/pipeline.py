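"""End-to-end analysis: endpoint transform -> correlations -> regime models.

``run_pipeline`` is a pure function of its inputs and configuration: given
the same tables and the same :class:`RunConfig` it produces byte-identical
output files (no clocks, locales or hidden state enter the outputs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .correlations import CorrelationMatrix, build_matrix, exclusion_subsets
from .potency import CensoringScenario, apply_scenario
from .regime import (
    ModelComparison,
    cooks_distance,
    compare_models,
    fit_linear,
    fit_quadratic,
    fit_segmented,
    split_regimes,
)
from .tables import (
    DescriptorTable,
    EndpointTable,
    read_descriptor_table,
    read_endpoint_table,
    write_results,
)

log = logging.getLogger(__name__)


def round_half_up(x: float, dp: int = 2) -> float:
    """Presentation rounding (half away from zero), e.g. 0.005 -> 0.01."""
    if isinstance(x, float) and (np.isnan(x) or np.isinf(x)):
        return x
    q = Decimal(10) ** -dp
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    descriptors_path: str | Path | None = None  # None -> packaged panel
    endpoints_path: str | Path | None = None
    scenario: str = "truncate200"
    # vasodilation subset rule: "exclusion_list" (the packaged high-affinity
    # exclusions) or a numeric threshold on chi_iam (high side excluded)
    vaso_rule: str | float = "exclusion_list"
    regime_x: str = "chi_iam"
    regime_y: str = "vasodilation_pct"
    dp: int = 2
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        CensoringScenario(self.scenario)  # validate
        if self.dp < 0:
            raise ValueError("dp must be >= 0")


@dataclass
class RunBundle:
    """Everything one pipeline run computed."""

    descriptors: DescriptorTable
    endpoints: EndpointTable
    matrix: CorrelationMatrix
    comparison: ModelComparison | None
    influence: pd.DataFrame | None
    fits: dict
    log_lines: list[str]
    paths: dict = field(default_factory=dict)


def _versions_block() -> list[str]:
    import click
    import scipy

    from . import __version__

    return [
        f"biochromtox {__version__}",
        f"numpy {np.__version__} | scipy {scipy.__version__} | "
        f"pandas {pd.__version__} | click {click.__version__}",
    ]


def run_pipeline(config: RunConfig) -> RunBundle:
    """Execute transform -> correlate -> regime models -> diagnostics.

    Writes the full output file set when ``config.out_dir`` is given; on a
    hard error any partially written outputs are removed before the error
    propagates.
    """
    lines: list[str] = []
    lines += _versions_block()
    lines.append(f"config: scenario={config.scenario} vaso_rule={config.vaso_rule} "
                 f"x={config.regime_x} y={config.regime_y} dp={config.dp}")

    descriptors = (
        read_descriptor_table(config.descriptors_path)
        if config.descriptors_path
        else datasets.load_descriptors()
    )
    endpoints_raw = (
        read_endpoint_table(config.endpoints_path)
        if config.endpoints_path
        else datasets.load_endpoints()
    )
    scenario = CensoringScenario(config.scenario)
    endpoints = apply_scenario(endpoints_raw, scenario)
    n_cens = sum(endpoints_raw.censored_counts().values())
    if n_cens:
        lines.append(
            f"WARN censoring: {n_cens} right-censored cells re-expressed under "
            f"{scenario.value}"
        )

    # vasodilation subset
    if config.vaso_rule == "exclusion_list":
        exclusions = datasets.default_exclusions()
    else:
        threshold = float(config.vaso_rule)
        x = descriptors.descriptors[config.regime_x]
        _, high = split_regimes(x, threshold)
        exclusions = {"vasodilation_pct": high}
    subsets = exclusion_subsets(endpoints, exclusions)
    lines.append(
        "vasodilation subset: excluded "
        + (", ".join(sorted(exclusions.get("vasodilation_pct", []))) or "none")
    )

    matrix = build_matrix(descriptors, endpoints, subsets=subsets)
    for cell in matrix.cells:
        if cell.missing:
            lines.append(
                f"cell ({cell.endpoint}, {cell.descriptor}): missing ({cell.note})"
            )
        else:
            lines.append(
                f"cell ({cell.endpoint}, {cell.descriptor}): n={cell.n} "
                f"r={round_half_up(cell.r, config.dp)} "
                f"rho={round_half_up(cell.rho, config.dp)}"
            )
    lines.append(
        "WARN pec50_daphnia: published reference coefficients for this endpoint "
        "are not reproducible from the packaged panel by direct recomputation; "
        "interpret this row with caution"
    )

    # two-regime modelling on complete (x, y) pairs
    comparison = None
    influence_frame = None
    fits: dict = {}
    xy = pd.concat(
        [descriptors.descriptors[config.regime_x],
         endpoints.values[config.regime_y]],
        axis=1,
    ).dropna()
    if len(xy) >= 6:
        x = xy.iloc[:, 0].to_numpy()
        y = xy.iloc[:, 1].to_numpy()
        fits = {
            "linear": fit_linear(x, y),
            "quadratic": fit_quadratic(x, y),
            "segmented": fit_segmented(x, y),
        }
        comparison = compare_models(list(fits.values()))
        seg = fits["segmented"]
        lines.append(
            f"regime model ({config.regime_y} ~ {config.regime_x}, n={seg.n}): "
            f"psi={seg.psi:.2f} r2_adj={seg.r2_adj:.3f} best_by_aic="
            f"{comparison.best_by_aic}"
        )
        report = cooks_distance(seg, index=xy.index)
        influence_frame = report.frame
        lines.append(
            f"influence: Cook's distance threshold 4/n = {report.threshold:.3f}; "
            f"flagged: {', '.join(map(str, report.flagged)) or 'none'}"
        )
    else:
        lines.append(
            f"regime model skipped: only {len(xy)} complete ({config.regime_x}, "
            f"{config.regime_y}) pairs"
        )

    bundle = RunBundle(
        descriptors=descriptors,
        endpoints=endpoints,
        matrix=matrix,
        comparison=comparison,
        influence=influence_frame,
        fits=fits,
        log_lines=lines,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        written: dict = {}
        try:
            models_json = None
            if comparison is not None:
                models_json = comparison.to_dict()
                models_json["x"] = config.regime_x
                models_json["y"] = config.regime_y
            written = write_results(
                out,
                matrix=matrix,
                models=models_json,
                diagnostics=influence_frame,
                log_lines=lines,
            )
        except Exception:
            for p in written.values():
                Path(p).unlink(missing_ok=True)
            raise
        bundle.paths = written
    return bundle
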