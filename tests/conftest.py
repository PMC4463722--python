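import numpy as np
import pytest

from toxknn import ChemicalRecord, Dataset, FingerprintMatrix, SimulationConfig, simulate


@pytest.fixture
def tiny_dataset() -> Dataset:
    """Six hand-written chemicals spanning both GHS classes."""
    recs = [
        ChemicalRecord("a1", ld50=100.0, loel=10.0, ghs_class=1),
        ChemicalRecord("a2", ld50=50.0, loel=5.0, ghs_class=1),
        ChemicalRecord("a3", ld50=2000.0, loel=200.0, ghs_class=1),
        ChemicalRecord("b1", ld50=3000.0, loel=300.0, ghs_class=2),
        ChemicalRecord("b2", ld50=5000.0, loel=500.0, ghs_class=2),
        ChemicalRecord("b3", ld50=9000.0, loel=900.0, ghs_class=2),
    ]
    return Dataset(recs)


@pytest.fixture
def tiny_fingerprints(tiny_dataset) -> FingerprintMatrix:
    """Class-separated 6x5 bit patterns aligned to tiny_dataset."""
    bits = np.array(
        [
            [1, 1, 0, 0, 1],
            [1, 1, 0, 0, 0],
            [1, 1, 1, 0, 0],
            [0, 0, 1, 1, 0],
            [0, 0, 1, 1, 1],
            [0, 0, 0, 1, 1],
        ],
        dtype=np.uint8,
    )
    return FingerprintMatrix(tiny_dataset.ids, [f"b{i}" for i in range(5)], bits)


@pytest.fixture
def sim_default():
    """One default-configuration synthetic dataset (118 chemicals, 79 bits)."""
    cfg = SimulationConfig(seed=11)
    ds, fp, truth = simulate(cfg)
    return cfg, ds, fp, truth
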