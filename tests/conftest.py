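from __future__ import annotations

import numpy as np
import pytest

from cmipred.evaluation import cross_validate
from cmipred.model import ModelConfig
from cmipred.synthetic import SyntheticConfig, generate_planted_graph, toy_fixture
from cmipred.training import TrainConfig

# Benchmark settings for the planted-graph recovery experiments: the
# generator defaults (200 x 100, rank 4, density 0.05, flip 0.01) with a
# training budget sized for that problem. Shared by the test suite and by
# scripts/acceptance.py.
BENCH_GRAPH_SEED = 0
BENCH_FOLD_SEED = 1
BENCH_MODEL = ModelConfig(K=2, D=32, seed=0)
BENCH_TRAIN = TrainConfig(
    lr=1e-3, batch_size=256, max_epochs=800, lambda_reg=1e-4,
    patience=80, val_fraction=0.1, seed=0,
)
# lighter budget for the many fits inside hyperparameter sweeps
SWEEP_TRAIN = TrainConfig(
    lr=1e-3, batch_size=256, max_epochs=200, lambda_reg=1e-4,
    patience=25, val_fraction=0.1, seed=0,
)


@pytest.fixture
def toy():
    return toy_fixture()


@pytest.fixture(scope="session")
def planted():
    return generate_planted_graph(SyntheticConfig(seed=BENCH_GRAPH_SEED))


@pytest.fixture(scope="session")
def planted_cv(planted):
    """Five-fold CV of the full pipeline on the planted benchmark (shared)."""
    return cross_validate(
        planted.graph, BENCH_MODEL, BENCH_TRAIN, k=5, seed=BENCH_FOLD_SEED
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
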