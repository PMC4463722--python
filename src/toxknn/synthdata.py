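"""Synthetic datasets with the statistical structure the method assumes,
plus the packaged worked-example LOEL tables.

The generator emulates the study setting the pipeline was designed for:
~118 chemicals carrying 79 opaque binary fingerprint bits, split roughly
70:48 between an acutely toxic class (LD50 <= 2000 mg/kg/day) and a
non-harmful class. A configurable subset of bits is class-informative
(class-specific template values flipped with Bernoulli noise); the remaining
bits are fair coins. LD50 is log-uniform within the class range, and the
chronic LOEL is coupled to LD50 through a latent log10 acute/chronic ratio —
there is deliberately no direct fingerprint->LOEL effect, so the generator
probes exactly the hypothesis the read-across exploits: fingerprint
similarity -> same acute class -> comparable dose range -> transferable LOEL.

Two verbatim worked-example tables (94 training and 24 test categories with
query/analog LOELs, the mean-based predicted LOEL and the printed fold
difference) ship as package data for exact regression tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .chemdata import (
    CLASS_NON_HARMFUL,
    CLASS_TOXIC,
    GHS_CLASS1_MAX_LD50,
    ChemicalRecord,
    Dataset,
    assign_classes,
    classify_ghs,
    stratified_split,
)
from .exceptions import ConfigurationError, DataValidationError
from .knn import KnnModel, predict_set, select_k
from .readacross import BIN_LT10, build_category, summarize
from .similarity import FingerprintMatrix
from . import validation

_LOG10_GHS = math.log10(GHS_CLASS1_MAX_LD50)

_FIXTURE_FILES = {
    "table2": "table2_training_loel.csv",
    "table3": "table3_test_loel.csv",
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic generator; defaults echo the 118-chemical,
    79-bit, 70:48 study setting."""

    n_chemicals: int = 118
    n_bits: int = 79
    class1_fraction: float = 70 / 118
    informative_bits: int = 8
    flip_noise: float = 0.1
    #: per-class LD50 ranges on the log10 mg/kg/day scale; class 1 must stay
    #: at or below the GHS boundary, class 2 strictly above it
    ld50_log10_range: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {
            CLASS_TOXIC: (-1.0, _LOG10_GHS),
            CLASS_NON_HARMFUL: (_LOG10_GHS, 4.0),
        }
    )
    #: latent log10(LD50/LOEL) ratio ~ Normal(mean, sd)
    acute_chronic_log10_ratio: tuple[float, float] = (1.0, 0.5)
    loel_noise_log10_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_chemicals < 2:
            raise ConfigurationError("need at least 2 chemicals")
        if not 1 <= self.n_bits:
            raise ConfigurationError("need at least 1 fingerprint bit")
        if not 0 <= self.informative_bits <= self.n_bits:
            raise ConfigurationError("informative_bits must lie in [0, n_bits]")
        if not 0.0 < self.class1_fraction < 1.0:
            raise ConfigurationError("class1_fraction must lie in (0, 1)")
        if not 0.0 <= self.flip_noise < 0.5:
            raise ConfigurationError("flip_noise must lie in [0, 0.5)")
        if self.loel_noise_log10_sd < 0 or self.acute_chronic_log10_ratio[1] < 0:
            raise ConfigurationError("noise standard deviations must be non-negative")
        lo1, hi1 = self.ld50_log10_range[CLASS_TOXIC]
        lo2, hi2 = self.ld50_log10_range[CLASS_NON_HARMFUL]
        if not (lo1 < hi1 <= _LOG10_GHS and _LOG10_GHS <= lo2 < hi2):
            raise ConfigurationError(
                "class LD50 ranges must respect the GHS boundary "
                f"(class 1 within (0, {GHS_CLASS1_MAX_LD50}], class 2 above)"
            )


def simulate(cfg: SimulationConfig) -> tuple[Dataset, FingerprintMatrix, dict]:
    """Draw one synthetic dataset; returns (dataset, fingerprints, truth).

    The truth record stores every latent draw (class assignment, informative
    templates, LD50, the acute/chronic ratio and the noise applied to LOEL)
    so recovery experiments can condition on them. Deterministic per seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_chemicals, cfg.n_bits

    classes = np.where(rng.random(n) < cfg.class1_fraction, CLASS_TOXIC, CLASS_NON_HARMFUL)
    if len(np.unique(classes)) < 2:
        raise ConfigurationError(
            "simulated dataset collapsed to a single class; adjust class1_fraction/n_chemicals"
        )

    # class templates on the informative bits: class 1 -> 1, class 2 -> 0
    bits = rng.integers(0, 2, size=(n, m), dtype=np.uint8)
    ni = cfg.informative_bits
    if ni:
        template = (classes == CLASS_TOXIC).astype(np.uint8)[:, None] * np.ones(ni, dtype=np.uint8)
        flips = (rng.random((n, ni)) < cfg.flip_noise).astype(np.uint8)
        bits[:, :ni] = template ^ flips

    log_ld50 = np.empty(n)
    for cls, (lo, hi) in cfg.ld50_log10_range.items():
        idx = classes == cls
        log_ld50[idx] = rng.uniform(lo, hi, size=int(idx.sum()))
    # class 2 sits strictly above the boundary
    log_ld50[classes == CLASS_NON_HARMFUL] = np.maximum(
        log_ld50[classes == CLASS_NON_HARMFUL], np.nextafter(_LOG10_GHS, np.inf)
    )

    mu, sd = cfg.acute_chronic_log10_ratio
    ratio = rng.normal(mu, sd, size=n)
    noise = rng.normal(0.0, cfg.loel_noise_log10_sd, size=n)
    log_loel = np.minimum(log_ld50 - ratio + noise, log_ld50)  # truncate: LOEL <= LD50

    width = len(str(n))
    ids = [f"chem_{i + 1:0{width}d}" for i in range(n)]
    records = [
        ChemicalRecord(
            id=ids[i],
            ld50=float(10.0 ** log_ld50[i]),
            loel=float(10.0 ** log_loel[i]),
            ghs_class=int(classes[i]),
        )
        for i in range(n)
    ]
    ds = Dataset(records, [f"simulated {n} chemicals, {m} bits, seed={cfg.seed}"])
    fp = FingerprintMatrix(ids, [f"bit_{j + 1}" for j in range(m)], bits)
    truth = {
        "classes": classes.tolist(),
        "informative_bits": ni,
        "log10_ld50": log_ld50.tolist(),
        "acute_chronic_log10_ratio": ratio.tolist(),
        "loel_noise_log10": noise.tolist(),
        "seed": cfg.seed,
    }
    # sanity: classes consistent with GHS rule by construction
    assert all(classify_ghs(r.ld50) == r.ghs_class for r in records)
    return ds, fp, truth


def load_fixture(table_id: str) -> pd.DataFrame:
    """Packaged worked-example LOEL table ('table2' training, 'table3' test).

    Columns: entry, query_loel, analog1..3_loel, printed_pred, printed_fold.
    Printed values are stored verbatim, including the rows whose printed fold
    difference is internally inconsistent (computed from the analog sum rather
    than the mean in the source table).
    """
    if table_id not in _FIXTURE_FILES:
        raise ConfigurationError(f"unknown fixture {table_id!r}; expected one of {sorted(_FIXTURE_FILES)}")
    ref = resources.files("toxknn.data").joinpath(_FIXTURE_FILES[table_id])
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def recovery_experiment(
    cfg: SimulationConfig,
    k_grid: Sequence[int] = tuple(range(1, 11)),
    folds: int = 5,
    seed: int = 0,
    train_fraction: float = 0.8,
    permute_loels: bool = False,
) -> dict:
    """End-to-end harness: simulate -> split -> select k -> predict -> read-across.

    With ``permute_loels`` the chronic endpoints are shuffled across chemicals
    after simulation (seeded), destroying the acute/chronic coupling while
    keeping the marginal LOEL distribution — the null against which the
    qualified-category success rate is judged.
    """
    ds, fp, _truth = simulate(cfg)
    if permute_loels:
        rng = np.random.default_rng(seed + 1)
        loels = np.array([r.loel for r in ds.records])
        perm = rng.permutation(len(loels))
        for r, v in zip(ds.records, loels[perm]):
            r.loel = float(min(v, r.ld50))  # keep the curation invariant
    ds = stratified_split(ds, train_fraction, seed)
    train = ds.subset_dataset("train")
    test = ds.subset_dataset("test")

    k_star, cv_table = select_k(train, fp, k_grid=k_grid, folds=folds, seed=seed)
    model = KnnModel(train.ids, [r.ghs_class for r in train.records], fp.select(train.ids), k_star)

    endpoints = {r.id: r for r in ds.records}
    results = {}
    for phase, queries in (("train", train), ("test", test)):
        preds = predict_set(model, fp.select(queries.ids), exclude_self=True)
        true = [r.ghs_class for r in queries.records]
        rep = validation.metrics(validation.confusion(true, [p for _, p in preds]), phase=phase, k=k_star)
        cats = [
            build_category(rec, neigh, pred, endpoints)
            for rec, (neigh, pred) in zip(queries.records, preds)
        ]
        summary = summarize(cats)
        n_qual = sum(c.qualified for c in cats)
        results[phase] = {
            "ner": rep.ner,
            "n": len(cats),
            "qualified_fraction": n_qual / len(cats) if cats else None,
            "qualified_fold_lt10_fraction": summary.success_rate_qualified,
        }

    cv_row = cv_table.loc[cv_table["k"] == k_star].iloc[0]
    return {
        "k": k_star,
        "cv_ner": float(cv_row["ner"]),
        "cv_table": cv_table,
        "train": results["train"],
        "test": results["test"],
    }
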