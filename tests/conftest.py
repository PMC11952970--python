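"""Shared fixtures.

The session-scoped ``e2e_run`` fixture executes the full training protocol
(fine-tune, stage 1, stage 2) once on the default planted-motif benchmark
(2000 train / 500 test, SAGGY at positions 20-24) and is shared by the
training, motif and acceptance tests to keep the suite within a desk-scale
budget.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from methylfusion import (FusionConfig, GeneratorConfig, MethylationPredictor,
                          TrainConfig, generate_dataset, train_test_split)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


def tiny_predictor(seed: int = 7, **train_overrides) -> MethylationPredictor:
    """Desk-scale model: 2 blocks, d_m=64, 2 heads, d=64 fusion."""
    return MethylationPredictor(
        encoder_config=dict(num_blocks=2, d_m=64, num_heads=2),
        fusion_config=FusionConfig(d=64, h_dec=32, embed_dim=64),
        train_config=TrainConfig(seed=seed, **train_overrides))


@pytest.fixture(scope="session")
def default_benchmark():
    """2000 train / 500 test balanced planted-motif records."""
    dataset = generate_dataset(GeneratorConfig(n_pos=1250, n_neg=1250, seed=11))
    return train_test_split(dataset, 0.8, 11)


@pytest.fixture(scope="session")
def e2e_run(default_benchmark):
    """Full protocol on the default benchmark; returns (model, train, test,
    test report)."""
    train, test = default_benchmark
    model = tiny_predictor(seed=7)
    model.fit(train, fine_tune_sets=[train], fine_tune_epochs=6,
              stage2_epochs=10)
    report = model.evaluate(test)
    return model, train, test, report


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
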