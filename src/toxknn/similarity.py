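"""Binary molecular fingerprints and Jaccard-Tanimoto distances.

Fingerprints are consumed as opaque named bits (e.g. the 79 electrotopological
Estate atom-type bits); computing them from structures is out of scope. The
distance between two fingerprints a, b is

    d(a, b) = 1 - |a AND b| / |a OR b|

counting set bits — the Jaccard distance, called Tanimoto in cheminformatics.
It is a metric on binary vectors (triangle inequality holds).

Conventions for all-zero fingerprints (not representable as set overlap):
d(0, 0) = 0 (identical objects) and d(0, x != 0) = 1 (maximally dissimilar to
any featured molecule). An all-zero fingerprint triggers a logged warning at
ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DataFormatError, DataValidationError

logger = logging.getLogger(__name__)


@dataclass
class FingerprintMatrix:
    """n chemicals x m named binary bits, row order aligned to a Dataset."""

    ids: list[str]
    bit_names: list[str]
    bits: np.ndarray  # shape (n, m), dtype uint8, entries in {0, 1}

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        n, m = self.bits.shape if self.bits.ndim == 2 else (len(self.bits), -1)
        if self.bits.ndim != 2 or n != len(self.ids) or m != len(self.bit_names):
            raise DataFormatError("fingerprint matrix shape does not match ids/bit_names")
        if len(self.bit_names) < 1:
            raise DataFormatError("fingerprint matrix needs at least one bit column")
        if len(set(self.ids)) != len(self.ids):
            raise DataValidationError("fingerprint ids must be unique")
        if not np.isin(self.bits, (0, 1)).all():
            raise DataValidationError("fingerprint entries must all be 0 or 1")
        zero_rows = np.flatnonzero(self.bits.sum(axis=1) == 0)
        for i in zero_rows:
            logger.warning("all-zero fingerprint for chemical %r", self.ids[i])

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, chem_id: str) -> np.ndarray:
        return self.bits[self.ids.index(chem_id)]

    def select(self, ids: Sequence[str]) -> "FingerprintMatrix":
        """Rows for ``ids``, in the given order."""
        index = {cid: i for i, cid in enumerate(self.ids)}
        missing = [c for c in ids if c not in index]
        if missing:
            raise DataValidationError(f"ids missing from fingerprint matrix: {', '.join(missing)}")
        rows = [index[c] for c in ids]
        return FingerprintMatrix(list(ids), list(self.bit_names), self.bits[rows])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.bits, columns=self.bit_names)
        df.insert(0, "id", self.ids)
        return df


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Jaccard-Tanimoto distances with zero diagonal."""

    ids: list[str]
    d: np.ndarray  # shape (n, n), entries in [0, 1]


def tanimoto_distance(a: Sequence[int], b: Sequence[int]) -> float:
    """Jaccard-Tanimoto distance between two binary vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise DataFormatError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.sum((a == 1) & (b == 1)))
    union = int(np.sum((a == 1) | (b == 1)))
    if union == 0:
        return 0.0  # both all-zero: identical objects
    return 1.0 - inter / union


def _pairwise_jaccard(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Dense |X| x |Y| Jaccard distance table over {0,1} matrices."""
    xf = x.astype(np.float64)
    yf = y.astype(np.float64)
    inter = xf @ yf.T
    union = xf.sum(axis=1)[:, None] + yf.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0  # both rows all-zero
    return np.clip(d, 0.0, 1.0)


def distance_matrix(fp: FingerprintMatrix) -> DistanceMatrix:
    """All pairwise distances among the rows of ``fp``."""
    d = _pairwise_jaccard(fp.bits, fp.bits)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(fp.ids), d)


def cross_distances(queries: FingerprintMatrix, refs: FingerprintMatrix) -> pd.DataFrame:
    """Rectangular query x reference distance table.

    Bit schemas must agree exactly (same names, same order).
    """
    if list(queries.bit_names) != list(refs.bit_names):
        raise DataFormatError("bit-name schema mismatch between query and reference fingerprints")
    d = _pairwise_jaccard(queries.bits, refs.bits)
    return pd.DataFrame(d, index=queries.ids, columns=refs.ids)


def read_fingerprints(path: str | Path, sep: str = ",") -> FingerprintMatrix:
    """Read a delimited fingerprint table: header ``id,<bit1>,<bit2>,...``.

    Bit column order is significant and preserved. Any cell outside {0, 1}
    is an error naming the offending row id and bit.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise DataFormatError(f"{path.name}: need an id column plus at least one bit column")
    id_col = df.columns[0]
    ids = [str(v) for v in df[id_col]]
    bit_names = [str(c) for c in df.columns[1:]]
    raw = df[df.columns[1:]].to_numpy()
    numeric = pd.DataFrame(raw).apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = ~np.isin(numeric, (0, 1)) | ~np.isfinite(numeric)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise DataValidationError(
            f"{path.name}: non-binary fingerprint cell at id {ids[i]!r}, bit {bit_names[j]!r}: {raw[i, j]!r}"
        )
    return FingerprintMatrix(ids, bit_names, numeric.astype(np.uint8))


def write_fingerprints(fp: FingerprintMatrix, path: str | Path) -> None:
    fp.to_frame().to_csv(path, index=False)
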