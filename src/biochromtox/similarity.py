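"""Tanimoto similarity over fingerprint bit vectors.

The module's contract starts at fixed-length binary fingerprints (by
default ECFP4-style: radius 2, 2048 bits); generating them from
structures is delegated to an optional adapter around a cheminformatics
toolkit.  Bit vectors are serialised in CSV as big-endian hex strings
(``numpy.packbits`` order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FingerprintVector:
    """A compound's binary fingerprint."""

    compound_id: str
    bits: np.ndarray  # uint8 0/1 vector
    radius: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bits", np.asarray(self.bits, dtype=np.uint8).clip(0, 1)
        )

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)

    @property
    def n_set(self) -> int:
        return int(self.bits.sum())

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, compound_id: str, n_bits: int, hex_string: str, radius: int = 2):
        raw = np.frombuffer(bytes.fromhex(hex_string), dtype=np.uint8)
        bits = np.unpackbits(raw)[:n_bits]
        return cls(compound_id, bits, radius)


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Tanimoto coefficient ``|a & b| / |a | b|`` in [0, 1].

    Two all-zero vectors have no defined overlap; the coefficient is
    reported as 0 with a warning.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    if union == 0:
        warnings.warn(
            f"both fingerprints empty ({a.compound_id}, {b.compound_id}); "
            "similarity reported as 0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    return inter / union


def similarity_matrix(fps: Sequence[FingerprintVector]) -> pd.DataFrame:
    """Full symmetric Tanimoto matrix, ordered as the input."""
    if len(fps) < 2:
        raise ValueError("need at least two fingerprints")
    lengths = {fp.n_bits for fp in fps}
    if len(lengths) > 1:
        raise ValueError(f"fingerprint lengths differ: {sorted(lengths)}")
    ids = [fp.compound_id for fp in fps]
    mat = np.ones((len(fps), len(fps)))
    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            mat[i, j] = mat[j, i] = tanimoto(fps[i], fps[j])
    return pd.DataFrame(mat, index=pd.Index(ids, name="compound_id"), columns=ids)


def read_fingerprints(path: str | Path) -> list[FingerprintVector]:
    """Read a ``compound_id,n_bits,bits_hex`` CSV."""
    df = pd.read_csv(path, dtype={"compound_id": str, "n_bits": int, "bits_hex": str})
    return [
        FingerprintVector.from_hex(r["compound_id"], int(r["n_bits"]), r["bits_hex"])
        for _, r in df.iterrows()
    ]


def write_fingerprints(fps: Sequence[FingerprintVector], path: str | Path) -> None:
    pd.DataFrame(
        {
            "compound_id": [fp.compound_id for fp in fps],
            "n_bits": [fp.n_bits for fp in fps],
            "bits_hex": [fp.to_hex() for fp in fps],
        }
    ).to_csv(path, index=False)


def fingerprints_from_smiles(
    smiles: dict[str, str], *, radius: int = 2, n_bits: int = 2048
) -> list[FingerprintVector]:
    """Optional adapter: Morgan/ECFP fingerprints from SMILES via RDKit.

    Requires the ``chem`` extra.  Bit patterns depend on the toolkit
    version, so persisted fingerprints — not structures — are the stable
    interchange format.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "fingerprints_from_smiles requires rdkit (install the 'chem' extra)"
        ) from exc
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = []
    for cid, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES for {cid!r}: {smi!r}")
        bits = np.zeros(n_bits, dtype=np.uint8)
        bits[list(gen.GetFingerprint(mol).GetOnBits())] = 1
        out.append(FingerprintVector(cid, bits, radius))
    return out
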