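"""Chemical endpoint tables: loading, curation, GHS classing and splitting.

A dataset is an ordered collection of chemicals, each carrying an acute oral
toxicity value (rat LD50, mg/kg/day) and a chronic endpoint (LOEL, the lowest
observed effect level from a repeated-dose study, mg/kg/day). Record order is
stable and acts as the alignment key for fingerprint matrices.

Curation applies the numeric plausibility rule only: a chemical whose LOEL
exceeds its LD50 (a chronic no-effect threshold above the acutely lethal dose)
indicates a fundamental problem with the underlying data and is discarded.
Structural curation (salts, mixtures, SMILES standardisation) is the caller's
responsibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataFormatError, DataValidationError

#: Two-class collapse of the Globally Harmonized Scheme: LD50 at or below this
#: dose (mg/kg/day) is class 1 ("highly toxic, toxic and harmful"), above it
#: class 2 ("non-harmful"). The boundary itself belongs to class 1.
GHS_CLASS1_MAX_LD50 = 2000.0

CLASS_TOXIC = 1
CLASS_NON_HARMFUL = 2

_REQUIRED_COLUMNS = ("id", "ld50", "loel")


@dataclass
class ChemicalRecord:
    """One chemical with its identifiers and endpoint values."""

    id: str
    ld50: float
    loel: float
    smiles: str | None = None
    ghs_class: int | None = None
    subset: str | None = None  # "train" | "test" | None

    def validate(self) -> None:
        if not self.id:
            raise DataValidationError("record with empty id")
        for name, value in (("ld50", self.ld50), ("loel", self.loel)):
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise DataValidationError(
                    f"record {self.id!r}: {name} must be a positive finite number, got {value!r}"
                )
        if self.ghs_class is not None and self.ghs_class not in (CLASS_TOXIC, CLASS_NON_HARMFUL):
            raise DataValidationError(f"record {self.id!r}: ghs_class must be 1 or 2")
        if self.subset is not None and self.subset not in ("train", "test"):
            raise DataValidationError(f"record {self.id!r}: subset must be 'train' or 'test'")


@dataclass
class Dataset:
    """Ordered chemicals plus a free-text provenance log of curation steps."""

    records: list[ChemicalRecord]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise DataValidationError(f"duplicate chemical ids: {', '.join(dupes)}")
        for r in self.records:
            r.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def by_id(self, chem_id: str) -> ChemicalRecord:
        for r in self.records:
            if r.id == chem_id:
                return r
        raise KeyError(chem_id)

    def subset_dataset(self, subset: str) -> "Dataset":
        """Records labelled ``subset`` ('train' or 'test'), order preserved."""
        recs = [replace(r) for r in self.records if r.subset == subset]
        return Dataset(recs, self.provenance + [f"selected subset={subset}: {len(recs)} records"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "ld50": [r.ld50 for r in self.records],
                "loel": [r.loel for r in self.records],
                "ghs_class": [r.ghs_class for r in self.records],
                "subset": [r.subset for r in self.records],
            }
        )


def classify_ghs(ld50: float) -> int:
    """Two-class GHS label from an acute LD50 (mg/kg/day).

    Class 1 (toxic) for LD50 <= 2000, class 2 (non-harmful) above.
    """
    if not (math.isfinite(ld50) and ld50 > 0):
        raise DataValidationError(f"ld50 must be positive and finite, got {ld50!r}")
    return CLASS_TOXIC if ld50 <= GHS_CLASS1_MAX_LD50 else CLASS_NON_HARMFUL


def assign_classes(ds: Dataset) -> Dataset:
    """Return a copy with ``ghs_class`` set from each record's LD50."""
    recs = [replace(r, ghs_class=classify_ghs(r.ld50)) for r in ds.records]
    return Dataset(recs, ds.provenance + ["assigned GHS classes from LD50 (threshold 2000 mg/kg/day)"])


def curate(ds: Dataset) -> Dataset:
    """Discard records whose LOEL exceeds their LD50.

    The boundary case LOEL == LD50 is kept: only strictly larger chronic
    thresholds are implausible. Idempotent.
    """
    kept = [replace(r) for r in ds.records if r.loel <= r.ld50]
    n_discarded = len(ds.records) - len(kept)
    return Dataset(
        kept,
        ds.provenance + [f"curation discarded {n_discarded} records with LOEL > LD50; {len(kept)} kept"],
    )


def stratified_split(ds: Dataset, train_fraction: float, seed: int) -> Dataset:
    """Label each record 'train' or 'test', stratified by GHS class.

    Within each class, round(train_fraction * n_class) records (half-up) are
    drawn at random for the training set; the remainder become the test set.
    Reproducible for a fixed seed. With 70 class-1 and 48 class-2 chemicals at
    fraction 0.8 this yields the canonical 56/14 and 38/10 split.
    """
    if not 0.0 < train_fraction <= 1.0:
        raise ConfigurationError(f"train_fraction must be in (0, 1], got {train_fraction}")
    classes = [r.ghs_class for r in ds.records]
    if any(c is None for c in classes):
        raise DataValidationError("stratified_split requires ghs_class on every record")
    rng = np.random.default_rng(seed)
    subset = [""] * len(ds.records)
    for cls in sorted(set(classes)):
        idx = [i for i, c in enumerate(classes) if c == cls]
        if len(idx) < 2 and train_fraction < 1.0:
            raise ConfigurationError(
                f"class {cls} has {len(idx)} member(s); at least 2 required for stratification"
            )
        n_train = int(math.floor(train_fraction * len(idx) + 0.5))
        order = rng.permutation(len(idx))
        for rank, j in enumerate(order):
            subset[idx[j]] = "train" if rank < n_train else "test"
    recs = [replace(r, subset=s) for r, s in zip(ds.records, subset)]
    n_train_total = subset.count("train")
    return Dataset(
        recs,
        ds.provenance
        + [
            f"stratified split (fraction={train_fraction}, seed={seed}): "
            f"{n_train_total} train / {len(recs) - n_train_total} test"
        ],
    )


def read_endpoints(path: str | Path, sep: str = ",") -> Dataset:
    """Read a delimited endpoint table into a :class:`Dataset`.

    Expected header: ``id,smiles,ld50,loel[,ghs_class][,subset]``; ``id``,
    ``ld50`` and ``loel`` are mandatory. Lines starting with ``#`` are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path.name}: missing mandatory column(s): {', '.join(missing)}")

    bad_ids: list[str] = []
    for col in ("ld50", "loel"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df["id"][~(numeric > 0) | ~np.isfinite(numeric)]
        bad_ids.extend(str(i) for i in bad)
        df[col] = numeric
    if bad_ids:
        raise DataValidationError(
            "non-positive or unparseable endpoint value(s) for id(s): "
            + ", ".join(sorted(set(bad_ids)))
        )

    records = []
    for row in df.itertuples(index=False):
        ghs = getattr(row, "ghs_class", None)
        ghs = int(ghs) if ghs is not None and not pd.isna(ghs) else None
        subset = getattr(row, "subset", None)
        subset = str(subset) if subset is not None and not pd.isna(subset) else None
        smiles = getattr(row, "smiles", None)
        smiles = str(smiles) if smiles is not None and not pd.isna(smiles) else None
        records.append(
            ChemicalRecord(
                id=str(row.id), ld50=float(row.ld50), loel=float(row.loel),
                smiles=smiles, ghs_class=ghs, subset=subset,
            )
        )
    return Dataset(records, [f"read {len(records)} records from {path.name}"])


def write_dataset(ds: Dataset, path: str | Path, include_provenance: bool = False) -> None:
    """Write the dataset as CSV; round-trips losslessly through read_endpoints.

    With ``include_provenance`` the curation log is prepended as ``#`` comments.
    """
    path = Path(path)
    frame = ds.to_frame()
    with open(path, "w") as fh:
        if include_provenance:
            for line in ds.provenance:
                fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)
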