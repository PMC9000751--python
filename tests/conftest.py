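import numpy as np
import pandas as pd
import pytest

from ranksig.matrix import ExpressionMatrix, ProbeGeneMap
from ranksig.synth import SimConfig, default_config, generate_experiment


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 probes × 2 samples with a tie in the second sample."""
    values = pd.DataFrame(
        {"s1": [5.0, 3.0, 1.0], "s2": [5.0, 5.0, 1.0]},
        index=pd.Index(["pA", "pB", "pC"], name="probe"),
    )
    return ExpressionMatrix(values)


@pytest.fixture
def simple_map() -> ProbeGeneMap:
    return ProbeGeneMap({"pA": "GENE1", "pB": "GENE1", "pC": "GENE2"})


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact study: 300 genes, 20 up / 20 down planted at ±2."""
    genes = [f"G{i:05d}" for i in range(1, 301)]
    up, down = genes[10:30], genes[50:70]
    return SimConfig(
        n_genes=300,
        n_background_series=3,
        samples_per_series=6,
        planted_de=[(g, 2.0) for g in up] + [(g, -2.0) for g in down],
        planted_sets=[("SET_UP", list(up), "up"), ("SET_DOWN", list(down), "down")],
        planted_drugs=[("MIMIC", 0.9), ("ANTI", 0.1)],
        planted_tf_modules=[(genes[100], list(up), list(down))],
        bank_size=40,
        n_decoy_sets=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return generate_experiment(small_config)


@pytest.fixture(scope="session")
def demo_config() -> SimConfig:
    return default_config(seed=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
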