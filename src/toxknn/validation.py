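"""Classification quality metrics for the two-class toxicity pipeline.

Definitions (two classes, rows of the confusion matrix are true classes):

* sensitivity of class c — fraction of true-c queries predicted c;
* specificity of class c — fraction of non-c queries predicted non-c
  (for two classes this equals the sensitivity of the other class);
* NER (non-error rate) — the mean of the per-class sensitivities, i.e.
  balanced accuracy;
* class error — 1 - sensitivity; mean class error — 1 - NER.

NER is deliberately the balanced rather than raw accuracy: it is the only
definition under which an NER of 0.74 corresponds to a mean class error of
0.26 for both classes at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .exceptions import DataFormatError
from ._rounding import round_half_up

logger = logging.getLogger(__name__)

CLASS_LABELS = (1, 2)


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_labels: tuple[int, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.class_labels)
        if self.counts.shape != (c, c) or (self.counts < 0).any():
            raise DataFormatError("confusion matrix must be square non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ValidationReport:
    """Per-phase summary of one classifier evaluation."""

    phase: str  # "fitting" | "cv" | "external"
    k: int | None
    ner: float
    sensitivity: dict[int, float | None]
    specificity: dict[int, float | None]
    class_error: dict[int, float | None]
    mean_class_error: float
    n: int
    fingerprint: str | None = None

    def rounded(self, ndigits: int = 2) -> dict:
        """Report-precision view (half-up, Table-style 2 decimals)."""
        r = lambda v: None if v is None else round_half_up(v, ndigits)
        return {
            "phase": self.phase,
            "k": self.k,
            "ner": r(self.ner),
            "sensitivity": {c: r(v) for c, v in self.sensitivity.items()},
            "specificity": {c: r(v) for c, v in self.specificity.items()},
            "class_error": {c: r(v) for c, v in self.class_error.items()},
            "mean_class_error": r(self.mean_class_error),
            "n": self.n,
        }


def confusion(true_classes: Sequence[int], predicted_classes: Sequence[int]) -> ConfusionMatrix:
    """Tally a confusion matrix over the fixed class labels (1, 2)."""
    t = np.asarray(true_classes)
    p = np.asarray(predicted_classes)
    if t.shape != p.shape:
        raise DataFormatError("true and predicted class vectors must have equal length")
    counts = _sk_confusion(t, p, labels=list(CLASS_LABELS))
    return ConfusionMatrix(counts)


def correct_count(true_classes: Sequence[int], predicted_classes: Sequence[int]) -> int:
    """Number of queries whose class was predicted correctly."""
    t = np.asarray(true_classes)
    p = np.asarray(predicted_classes)
    if t.shape != p.shape:
        raise DataFormatError("true and predicted class vectors must have equal length")
    return int((t == p).sum())


def metrics(
    cm: ConfusionMatrix,
    phase: str = "cv",
    k: int | None = None,
    fingerprint: str | None = None,
) -> ValidationReport:
    """Derive NER, per-class sensitivity/specificity and class errors.

    A class absent from the evaluated queries has undefined sensitivity; it is
    reported as missing, excluded from the NER mean, and logged as a warning.
    """
    labels = cm.class_labels
    if len(labels) != 2:
        raise DataFormatError("metrics are defined for the two-class pipeline only")
    sens: dict[int, float | None] = {}
    for i, c in enumerate(labels):
        row_total = cm.counts[i].sum()
        if row_total == 0:
            logger.warning("phase %s: no true class-%s queries; sensitivity undefined", phase, c)
            sens[c] = None
        else:
            sens[c] = float(cm.counts[i, i] / row_total)
    # two-class mirror: specificity of one class is the sensitivity of the other
    spec = {labels[0]: sens[labels[1]], labels[1]: sens[labels[0]]}
    defined = [v for v in sens.values() if v is not None]
    ner = float(np.mean(defined)) if defined else float("nan")
    class_error = {c: None if v is None else 1.0 - v for c, v in sens.items()}
    report = ValidationReport(
        phase=phase,
        k=k,
        ner=ner,
        sensitivity=sens,
        specificity=spec,
        class_error=class_error,
        mean_class_error=1.0 - ner,
        n=cm.total,
        fingerprint=fingerprint,
    )
    # internal consistency: the mirror identity must hold on every report
    assert report.specificity[labels[0]] == report.sensitivity[labels[1]]
    assert report.specificity[labels[1]] == report.sensitivity[labels[0]]
    return report


def model_comparison_report(reports: Sequence[ValidationReport]) -> pd.DataFrame:
    """Rank fingerprint models: external NER, then CV NER, then smaller k.

    ``reports`` holds fitting/cv/external entries tagged with a fingerprint
    name; the output has one row per fingerprint per phase, best model first.
    """
    rows = [
        {
            "fingerprint": r.fingerprint or "",
            "phase": r.phase,
            "NER": round_half_up(r.ner, 2),
            "k": r.k,
            "sens_c1": None if r.sensitivity[1] is None else round_half_up(r.sensitivity[1], 2),
            "sens_c2": None if r.sensitivity[2] is None else round_half_up(r.sensitivity[2], 2),
            "spec_c1": None if r.specificity[1] is None else round_half_up(r.specificity[1], 2),
            "spec_c2": None if r.specificity[2] is None else round_half_up(r.specificity[2], 2),
        }
        for r in reports
    ]
    df = pd.DataFrame(rows)
    key: dict[str, tuple] = {}
    for name in df["fingerprint"].unique():
        sub = df[df["fingerprint"] == name]
        ext = sub.loc[sub["phase"] == "external", "NER"]
        cv = sub.loc[sub["phase"] == "cv", "NER"]
        kvals = [v for v in sub["k"] if v is not None]
        key[name] = (
            -(float(ext.iloc[0]) if len(ext) else -np.inf),
            -(float(cv.iloc[0]) if len(cv) else -np.inf),
            min(kvals) if kvals else np.inf,
        )
    phase_order = {"fitting": 0, "cv": 1, "external": 2}
    df["_rank"] = df["fingerprint"].map(key)
    df["_phase"] = df["phase"].map(phase_order)
    df = df.sort_values(["_rank", "_phase"], kind="stable").drop(columns=["_rank", "_phase"])
    return df.reset_index(drop=True)
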