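"""Category formation and read-across prediction of chronic LOEL values.

Each query chemical together with its k nearest analogs forms a *category*.
The query's LOEL is predicted as the arithmetic mean of the analog LOELs. A
category is *qualified* when the k-NN model predicted the query's LD50-derived
class correctly — the gate for trusting the read-across. Prediction quality is
summarised by the *fold difference*, the larger/smaller ratio of experimental
and predicted LOEL (orientation-free, always >= 1), binned into order-of-
magnitude bands: < 10, 10–100 (boundaries inclusive), > 100.

Read-across is computed for every query; qualification filters summaries but
never suppresses a prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemdata import ChemicalRecord
from .exceptions import DataValidationError
from .knn import NeighborList
from ._rounding import round_half_up

BIN_LT10 = "lt10"
BIN_10_100 = "from10to100"
BIN_GT100 = "gt100"
BINS = (BIN_LT10, BIN_10_100, BIN_GT100)


@dataclass
class AnalogEndpoint:
    analog_id: str
    distance: float
    ld50_class: int
    loel: float


@dataclass
class Category:
    """One query with its analogs and the derived read-across quantities."""

    query_id: str
    analogs: list[AnalogEndpoint]
    true_class: int
    predicted_class: int
    qualified: bool
    experimental_loel: float
    predicted_loel: float
    fold_diff: float
    bin: str
    extrapolated: bool


@dataclass
class ReadAcrossSummary:
    """Order-of-magnitude counts split by category qualification."""

    counts: pd.DataFrame  # rows BINS + "total", columns qualified/non_qualified/total
    success_rate_qualified: float | None  # fraction of qualified categories with fold < 10


def predict_loel(analog_loels: Sequence[float]) -> float:
    """Arithmetic mean of the analog LOELs (mg/kg/day)."""
    loels = [float(x) for x in analog_loels]
    if not loels:
        raise DataValidationError("cannot predict a LOEL from an empty analog list")
    if any(not np.isfinite(x) or x <= 0 for x in loels):
        raise DataValidationError(f"analog LOELs must be positive, got {loels}")
    return float(np.mean(loels))


def fold_difference(experimental_loel: float, predicted_loel: float) -> float:
    """Orientation-free ratio max/min of experimental and predicted LOEL."""
    a, b = float(experimental_loel), float(predicted_loel)
    if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
        raise DataValidationError(f"LOELs must be positive, got ({a}, {b})")
    return max(a, b) / min(a, b)


def assign_bin(fold_diff: float) -> str:
    """Order-of-magnitude band; 10 and 100 belong to the middle bin."""
    if fold_diff < 1.0:
        raise DataValidationError(f"fold difference must be >= 1, got {fold_diff}")
    if fold_diff < 10.0:
        return BIN_LT10
    if fold_diff <= 100.0:
        return BIN_10_100
    return BIN_GT100


def flag_extrapolation(experimental_loel: float, analog_loels: Sequence[float]) -> bool:
    """True when the query's experimental LOEL lies strictly outside the
    range spanned by its analogs' LOELs (the read-across had to extrapolate)."""
    loels = [float(x) for x in analog_loels]
    return experimental_loel < min(loels) or experimental_loel > max(loels)


def build_category(
    query: ChemicalRecord,
    neigh: NeighborList,
    predicted_class: int,
    endpoints: Mapping[str, ChemicalRecord],
) -> Category:
    """Assemble a fully populated category for one query.

    ``endpoints`` resolves each analog id to its record (LOEL and class).
    """
    analogs = []
    for n in neigh.neighbors:
        rec = endpoints.get(n.ref_id)
        if rec is None or rec.loel is None:
            raise DataValidationError(f"analog {n.ref_id!r} has no resolvable LOEL")
        analogs.append(AnalogEndpoint(n.ref_id, n.distance, n.ref_class, rec.loel))
    if query.ghs_class is None:
        raise DataValidationError(f"query {query.id!r} has no GHS class")
    loels = [a.loel for a in analogs]
    pred = predict_loel(loels)
    fold = fold_difference(query.loel, pred)
    return Category(
        query_id=query.id,
        analogs=analogs,
        true_class=query.ghs_class,
        predicted_class=predicted_class,
        qualified=(predicted_class == query.ghs_class),
        experimental_loel=query.loel,
        predicted_loel=pred,
        fold_diff=fold,
        bin=assign_bin(fold),
        extrapolated=flag_extrapolation(query.loel, loels),
    )


def summarize(categories: Sequence[Category]) -> ReadAcrossSummary:
    """3x2 bin-by-qualification count grid with totals and the success rate
    (qualified categories predicted within a factor of 10)."""
    grid = pd.DataFrame(0, index=list(BINS) + ["total"], columns=["qualified", "non_qualified", "total"])
    for cat in categories:
        col = "qualified" if cat.qualified else "non_qualified"
        grid.loc[cat.bin, col] += 1
    grid["total"] = grid["qualified"] + grid["non_qualified"]
    grid.loc["total"] = grid.loc[list(BINS)].sum()
    n_qual = int(grid.loc["total", "qualified"])
    rate = float(grid.loc[BIN_LT10, "qualified"] / n_qual) if n_qual else None
    return ReadAcrossSummary(grid, rate)


def readacross_report(categories: Sequence[Category]) -> pd.DataFrame:
    """One row per query with analog LOELs, predicted LOEL and fold difference
    at report precision (2 decimals, half-up); wide analog columns repeat to k."""
    if not categories:
        return pd.DataFrame()
    k = max(len(c.analogs) for c in categories)
    rows = []
    for c in categories:
        row: dict = {"query_id": c.query_id, "exp_loel": c.experimental_loel}
        for i in range(k):
            a = c.analogs[i] if i < len(c.analogs) else None
            row[f"analog{i+1}_id"] = a.analog_id if a else None
            row[f"analog{i+1}_loel"] = a.loel if a else None
        row.update(
            pred_loel=round_half_up(c.predicted_loel, 2),
            fold_diff=round_half_up(c.fold_diff, 2),
            qualified=c.qualified,
            bin=c.bin,
            extrapolated=c.extrapolated,
        )
        rows.append(row)
    return pd.DataFrame(rows)
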