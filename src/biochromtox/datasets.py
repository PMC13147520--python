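"""Packaged reference panel: 18 bisphenol analogues.

The shipped CSVs carry the printed descriptor and endpoint values for the
bisphenol panel (lipophilicity indices, gradient CHI on C18 and
phosphatidylcholine-IAM phases, isocratic sphingomyelin log k, plus
cytotoxicity pIC50 in four cell lines, ex vivo vasodilation, and Daphnia
pEC50).  Potency values are on the truncate200 censoring scenario; the
six cells equal to 3.70 (= -log10 of 200 uM) are flagged censored.

``standards_synthetic.csv`` is a synthetic example of a CHI calibration
standards file — plausible in scale but NOT literature reference values.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .tables import DescriptorTable, EndpointTable, read_descriptor_table, read_endpoint_table

#: Compounds excluded from the vasodilation correlation subset: the
#: high-membrane-affinity regime (CHI on the phosphatidylcholine IAM
#: phase above ~50) in which vasodilation declines with lipophilicity.
VASODILATION_EXCLUSIONS = ("BPZ", "BPG", "BPP", "BPPH", "BPBP")


def _data_path(name: str) -> Path:
    return Path(resources.files("biochromtox.data") / name)


def load_descriptors() -> DescriptorTable:
    """The descriptor panel (18 compounds, 9 descriptor columns).

    Three compounds (BPG, BPBP, BPPH) did not elute from the sphingomyelin
    column, so their ``logk_iam_sph`` cells are missing.
    """
    return read_descriptor_table(_data_path("table1.csv"))


def load_endpoints() -> EndpointTable:
    """The endpoint panel (truncate200 scenario, censor flags set)."""
    return read_endpoint_table(_data_path("table2.csv"), scenario="truncate200")


def load_fingerprints():
    """Precomputed ECFP4 (radius 2, 2048-bit) fingerprints for the panel."""
    from .similarity import read_fingerprints

    return read_fingerprints(_data_path("fingerprints.csv"))


def load_standards_synthetic() -> pd.DataFrame:
    """Synthetic CHI calibration-standards example (``name,t_r_min,chi_ref``)."""
    return pd.read_csv(_data_path("standards_synthetic.csv"))


def default_exclusions() -> dict[str, list[str]]:
    """Endpoint -> excluded-compound map used by the reference analysis.

    Only the vasodilation endpoint is restricted: the five high-affinity
    compounds are excluded, leaving the n=8 low-to-moderate subset.
    """
    return {"vasodilation_pct": list(VASODILATION_EXCLUSIONS)}
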