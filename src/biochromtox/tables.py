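"""Tabular I/O for compound descriptor and toxicity-endpoint panels.

All tables are wide, one compound per row, keyed by ``compound_id``.
Missing values are accepted on input as blank cells or the tokens
``N.D`` / ``N.A.`` / ``NA`` (case-insensitive, with or without trailing
dots); written output always uses blank cells.  Internally missing cells
are ``NaN``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Descriptor columns, in the fixed order of the descriptor panel.
DESCRIPTOR_COLUMNS = (
    "acd_logp_classic",
    "consensus_logp_acd",
    "acd_logp_galas",
    "acd_logd",
    "logp_chemicalize",
    "logd_chemicalize",
    "chi_c18",
    "chi_iam",
    "logk_iam_sph",
)

#: Endpoint columns, in fixed order.
ENDPOINT_COLUMNS = (
    "pic50_3t3l1",
    "pic50_mcf7",
    "pic50_c6",
    "pic50_hela",
    "vasodilation_pct",
    "pec50_daphnia",
)

#: Cytotoxicity potency columns that may carry right-censor flags.
POTENCY_COLUMNS = (
    "pic50_3t3l1",
    "pic50_mcf7",
    "pic50_c6",
    "pic50_hela",
)

_COMPOUND_META = ("name", "cas", "smiles", "mw")

_MISSING_TOKENS = frozenset({"", "nd", "na"})


def _is_missing(token: str) -> bool:
    return token.strip().replace(".", "").lower() in _MISSING_TOKENS


def _parse_cell(token: str, *, row: str, column: str) -> float:
    token = token.strip()
    if _is_missing(token):
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"non-numeric cell {token!r} at row {row!r}, column {column!r}"
        ) from None


@dataclass
class DescriptorTable:
    """Per-compound lipophilicity descriptors plus compound metadata.

    ``frame`` is indexed by ``compound_id`` and holds the metadata columns
    (``name``, ``cas``, ``smiles``, ``mw``) followed by the nine descriptor
    columns of :data:`DESCRIPTOR_COLUMNS`.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate compound_id: {dups}")
        mw = pd.to_numeric(self.frame.get("mw"), errors="coerce")
        if mw is not None and (mw.dropna() <= 0).any():
            raise ValueError("mw must be > 0 when present")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def descriptors(self) -> pd.DataFrame:
        """The numeric descriptor block only, fixed column order."""
        return self.frame.loc[:, list(DESCRIPTOR_COLUMNS)]

    @property
    def mw(self) -> pd.Series:
        return pd.to_numeric(self.frame["mw"], errors="coerce")

    def n_missing(self, column: str) -> int:
        return int(self.frame[column].isna().sum())

    def write(self, path: str | Path) -> None:
        df = self.frame.reset_index()
        df.to_csv(path, index=False, na_rep="")


@dataclass
class EndpointTable:
    """Per-compound toxicity endpoints with right-censoring flags.

    ``values`` is indexed by ``compound_id`` with the six endpoint columns
    of :data:`ENDPOINT_COLUMNS`; ``censored`` is a boolean frame over the
    cytotoxicity potency columns only (a ``True`` marks a value originally
    reported as exceeding the assay ceiling).  ``scenario`` records which
    censoring treatment produced the stored potency values.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    scenario: str = "truncate200"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate compound_id in endpoint table")
        vaso = self.values["vasodilation_pct"].dropna()
        bad = vaso[(vaso < 0) | (vaso > 100)]
        if len(bad):
            raise ValueError(
                f"vasodilation_pct outside [0, 100] for {bad.index.tolist()}"
            )
        extra = set(self.censored.columns) - set(POTENCY_COLUMNS)
        if extra:
            raise ValueError(f"censor flags only allowed on potency columns, got {extra}")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    def counts(self) -> dict[str, int]:
        """Non-missing count per endpoint column."""
        return {c: int(self.values[c].notna().sum()) for c in ENDPOINT_COLUMNS}

    def censored_counts(self) -> dict[str, int]:
        return {c: int(self.censored[c].sum()) for c in POTENCY_COLUMNS}

    def write(self, path: str | Path) -> None:
        out = pd.DataFrame(index=self.values.index)
        for col in POTENCY_COLUMNS:
            out[col] = self.values[col]
            out["cens_" + col.removeprefix("pic50_")] = self.censored[col].astype(int)
        out["vasodilation_pct"] = self.values["vasodilation_pct"]
        out["pec50_daphnia"] = self.values["pec50_daphnia"]
        out.reset_index().to_csv(path, index=False, na_rep="")


def read_descriptor_table(path: str | Path) -> DescriptorTable:
    """Read a wide descriptor CSV (``descriptors.csv`` schema).

    Blank cells and ``N.D``-style tokens parse to missing; any other
    non-numeric cell is a hard error naming its row and column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["compound_id", *_COMPOUND_META, *DESCRIPTOR_COLUMNS]
    missing_cols = [c for c in expected if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"descriptor table missing columns: {missing_cols}")
    frame = raw.set_index("compound_id")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].tolist()
        raise ValueError(f"duplicate compound_id: {dups}")
    for col in ("mw", *DESCRIPTOR_COLUMNS):
        frame[col] = [
            _parse_cell(v, row=i, column=col) for i, v in frame[col].items()
        ]
    table = DescriptorTable(frame.loc[:, [*_COMPOUND_META, *DESCRIPTOR_COLUMNS]])
    log.info(
        "read descriptor table: %d compounds (%s)",
        len(table.frame),
        ", ".join(table.compound_ids),
    )
    return table


def read_endpoint_table(path: str | Path, scenario: str = "truncate200") -> EndpointTable:
    """Read a wide endpoint CSV (``endpoints.csv`` schema) with censor flags."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "compound_id" not in raw.columns:
        raise ValueError("endpoint table missing compound_id column")
    frame = raw.set_index("compound_id")
    values = pd.DataFrame(index=frame.index)
    censored = pd.DataFrame(False, index=frame.index, columns=list(POTENCY_COLUMNS))
    for col in ENDPOINT_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"endpoint table missing column {col!r}")
        values[col] = [
            _parse_cell(v, row=i, column=col) for i, v in frame[col].items()
        ]
    for col in POTENCY_COLUMNS:
        flag_col = "cens_" + col.removeprefix("pic50_")
        if flag_col in frame.columns:
            flags = frame[flag_col].str.strip().replace("", "0")
            if not flags.isin({"0", "1"}).all():
                raise ValueError(f"{flag_col} must be 0/1")
            censored[col] = flags.astype(int).astype(bool)
    table = EndpointTable(values, censored, scenario=scenario)
    log.info("read endpoint table: per-column n = %s", table.counts())
    return table


def with_values(table: EndpointTable, values: pd.DataFrame, scenario: str) -> EndpointTable:
    """A copy of ``table`` with replaced endpoint values and scenario tag."""
    return replace(table, values=values, scenario=scenario)


def write_results(
    out_dir: str | Path,
    matrix=None,
    models=None,
    diagnostics: pd.DataFrame | None = None,
    similarity: pd.DataFrame | None = None,
    log_lines: list[str] | None = None,
) -> dict[str, Path]:
    """Write the analysis output file set with deterministic names/bytes.

    Parameters are the computed artefacts: ``matrix`` (a
    :class:`~biochromtox.correlations.CorrelationMatrix`), ``models`` (a
    JSON-serialisable model-comparison mapping), ``diagnostics`` (the
    influence frame), ``similarity`` (square Tanimoto frame) and the run
    log lines.  Only artefacts that are passed are written.
    """
    import json

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} not writable: {exc}") from exc

    written: dict[str, Path] = {}
    if matrix is not None:
        p = out / "correlation_matrix.csv"
        matrix.to_frame().to_csv(p, index=False, na_rep="")
        written["correlation_matrix"] = p
    if models is not None:
        p = out / "model_comparison.json"
        p.write_text(json.dumps(models, indent=2, sort_keys=True) + "\n")
        written["model_comparison"] = p
    if diagnostics is not None:
        p = out / "influence.csv"
        diagnostics.to_csv(p, index=True, na_rep="")
        written["influence"] = p
    if similarity is not None:
        p = out / "similarity_matrix.csv"
        similarity.to_csv(p, index=True, na_rep="")
        written["similarity"] = p
    if log_lines is not None:
        p = out / "run_log.txt"
        p.write_text("\n".join(log_lines) + "\n")
        written["run_log"] = p
    return written
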