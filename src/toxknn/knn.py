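"""k-nearest-neighbour classification over fingerprint space.

A query's class is the majority class of its k closest reference chemicals
under Jaccard-Tanimoto distance. Deterministic tie rules:

* rank ties at the k-th neighbour: stable ascending sort by
  (distance, reference input order);
* vote ties (possible for even k): the class with the smaller summed
  neighbour distance wins; if still tied, class 1 (the conservative toxic
  call).

The optimal k is chosen by stratified cross-validation ("venetian blinds":
within each class, records are dealt round-robin into folds after a seeded
shuffle); each fold is predicted from the others and the k with the lowest
mean class error (1 - NER, where NER is the mean of per-class sensitivities)
wins, ties going to the smallest k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chemdata import CLASS_TOXIC, Dataset
from .exceptions import ConfigurationError, DataFormatError, DataValidationError
from .similarity import FingerprintMatrix, _pairwise_jaccard
from . import validation

DISTANCE_NAME = "jaccard-tanimoto"


@dataclass
class Neighbor:
    ref_id: str
    distance: float
    ref_class: int


@dataclass
class NeighborList:
    """The k analogs of one query, ascending by (distance, input order)."""

    query_id: str
    neighbors: list[Neighbor]

    def __len__(self) -> int:
        return len(self.neighbors)

    @property
    def classes(self) -> list[int]:
        return [n.ref_class for n in self.neighbors]

    @property
    def ids(self) -> list[str]:
        return [n.ref_id for n in self.neighbors]


@dataclass
class KnnModel:
    """Reference chemicals, their classes and fingerprints, plus the chosen k."""

    ref_ids: list[str]
    ref_classes: list[int]
    ref_fingerprints: FingerprintMatrix
    k: int

    def __post_init__(self) -> None:
        if not 1 <= self.k <= len(self.ref_ids):
            raise ConfigurationError(f"k={self.k} outside [1, {len(self.ref_ids)}]")
        if len(self.ref_classes) != len(self.ref_ids) or len(self.ref_fingerprints.ids) != len(self.ref_ids):
            raise DataFormatError("reference ids, classes and fingerprints must align")
        if any(c not in (1, 2) for c in self.ref_classes):
            raise DataValidationError("reference classes must be 1 or 2")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "distance": DISTANCE_NAME,
            "k": self.k,
            "ref_ids": self.ref_ids,
            "ref_classes": self.ref_classes,
            "bit_names": self.ref_fingerprints.bit_names,
            "bits": self.ref_fingerprints.bits.tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "KnnModel":
        doc = json.loads(Path(path).read_text())
        fp = FingerprintMatrix(doc["ref_ids"], doc["bit_names"], np.asarray(doc["bits"]))
        return cls(doc["ref_ids"], [int(c) for c in doc["ref_classes"]], fp, int(doc["k"]))


def _neighbor_list(
    model: KnnModel, dist_row: np.ndarray, query_id: str, exclude_self: bool
) -> NeighborList:
    order = np.argsort(dist_row, kind="stable")  # stable: ties by input order
    picked: list[Neighbor] = []
    for j in order:
        if exclude_self and model.ref_ids[j] == query_id:
            continue
        picked.append(Neighbor(model.ref_ids[j], float(dist_row[j]), model.ref_classes[j]))
        if len(picked) == model.k:
            break
    if len(picked) < model.k:
        raise ConfigurationError(
            f"k={model.k} exceeds the {len(picked)} available references for query {query_id!r}"
        )
    return NeighborList(query_id, picked)


def find_neighbors(
    model: KnnModel,
    query_bits: Sequence[int],
    query_id: str = "",
    exclude_self: bool = True,
) -> NeighborList:
    """The k references closest to one query fingerprint."""
    q = np.asarray(query_bits, dtype=np.uint8)[None, :]
    if q.shape[1] != len(model.ref_fingerprints.bit_names):
        raise DataFormatError("query fingerprint length does not match model bit schema")
    dist = _pairwise_jaccard(q, model.ref_fingerprints.bits)[0]
    return _neighbor_list(model, dist, query_id, exclude_self)


def predict_class(neigh: NeighborList) -> int:
    """Majority vote over neighbour classes with deterministic tie-breaks."""
    if len(neigh) == 0:
        raise ConfigurationError("cannot predict from an empty neighbour list")
    votes: dict[int, int] = {}
    summed: dict[int, float] = {}
    for n in neigh.neighbors:
        votes[n.ref_class] = votes.get(n.ref_class, 0) + 1
        summed[n.ref_class] = summed.get(n.ref_class, 0.0) + n.distance
    best = max(votes.values())
    tied = sorted(c for c, v in votes.items() if v == best)
    if len(tied) == 1:
        return tied[0]
    dmin = min(summed[c] for c in tied)
    closest = [c for c in tied if summed[c] == dmin]
    return CLASS_TOXIC if len(closest) > 1 else closest[0]


def predict_set(
    model: KnnModel,
    queries: FingerprintMatrix,
    exclude_self: bool = True,
) -> list[tuple[NeighborList, int]]:
    """Neighbour lists and predicted classes for every query row.

    With ``exclude_self`` (default), a query whose id occurs among the
    references never counts itself as an analog; switch it off to measure
    fitting (resubstitution) performance.
    """
    dist = _pairwise_jaccard(queries.bits, model.ref_fingerprints.bits)
    out = []
    for i, qid in enumerate(queries.ids):
        neigh = _neighbor_list(model, dist[i], qid, exclude_self)
        out.append((neigh, predict_class(neigh)))
    return out


def neighbor_table(results: Iterable[tuple[NeighborList, int]]) -> pd.DataFrame:
    """Long-format export: one row per (query, rank) pair."""
    rows = []
    for neigh, pred in results:
        for rank, n in enumerate(neigh.neighbors, start=1):
            rows.append(
                {
                    "query_id": neigh.query_id,
                    "rank": rank,
                    "analog_id": n.ref_id,
                    "distance": n.distance,
                    "analog_class": n.ref_class,
                    "predicted_class": pred,
                }
            )
    return pd.DataFrame(rows)


def venetian_blind_folds(classes: Sequence[int], folds: int, seed: int) -> np.ndarray:
    """Stratified fold labels: per class, round-robin after a seeded shuffle."""
    if folds < 2:
        raise ConfigurationError(f"folds must be >= 2, got {folds}")
    classes = np.asarray(classes)
    rng = np.random.default_rng(seed)
    fold = np.empty(len(classes), dtype=int)
    for cls in np.unique(classes):
        idx = np.flatnonzero(classes == cls)
        idx = idx[rng.permutation(len(idx))]
        fold[idx] = np.arange(len(idx)) % folds
    return fold


def select_k(
    train: Dataset,
    fp: FingerprintMatrix,
    k_grid: Sequence[int] = tuple(range(1, 11)),
    folds: int = 5,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Cross-validated choice of k.

    For each candidate k, every fold is predicted from the remaining folds and
    the pooled predictions are scored; the k with the lowest mean class error
    (ties to the smallest k) is returned together with the per-k table.
    """
    if not k_grid:
        raise ConfigurationError("k_grid must be non-empty")
    classes = [r.ghs_class for r in train.records]
    if any(c is None for c in classes):
        raise DataValidationError("select_k requires ghs_class on every training record")
    fp = fp.select(train.ids)
    fold = venetian_blind_folds(classes, folds, seed)
    classes_arr = np.asarray(classes)
    max_k = max(k_grid)

    pooled_pred = {k: np.zeros(len(classes), dtype=int) for k in k_grid}
    dist_all = _pairwise_jaccard(fp.bits, fp.bits)
    for f in range(folds):
        test_idx = np.flatnonzero(fold == f)
        ref_idx = np.flatnonzero(fold != f)
        if len(ref_idx) < max_k:
            raise ConfigurationError(f"fold {f}: only {len(ref_idx)} references for k={max_k}")
        ref_model_ids = [train.ids[i] for i in ref_idx]
        ref_fp = FingerprintMatrix(ref_model_ids, list(fp.bit_names), fp.bits[ref_idx])
        for k in k_grid:
            model = KnnModel(ref_model_ids, [int(classes_arr[i]) for i in ref_idx], ref_fp, k)
            for i in test_idx:
                neigh = _neighbor_list(model, dist_all[i, ref_idx], train.ids[i], exclude_self=False)
                pooled_pred[k][i] = predict_class(neigh)

    rows = []
    for k in k_grid:
        cm = validation.confusion(classes_arr, pooled_pred[k])
        rep = validation.metrics(cm, phase="cv", k=k)
        rows.append(
            {
                "k": k,
                "ner": rep.ner,
                "mean_class_error": rep.mean_class_error,
                "sens_c1": rep.sensitivity[1],
                "sens_c2": rep.sensitivity[2],
            }
        )
    table = pd.DataFrame(rows)
    best = table.sort_values(["mean_class_error", "k"], kind="stable").iloc[0]
    return int(best["k"]), table
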