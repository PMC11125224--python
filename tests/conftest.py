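"""Shared fixtures.

The expensive trained-model fixtures are session-scoped so the
learnability, attention-localization and ordinal-loss comparisons share
training runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from stagcn.model import ModelConfig
from stagcn.pipeline import RunConfig, train
from stagcn.synth import SynthConfig, generate_dataset, make_topology

# the separable study conditions: 4 levels, 40 samples/class, 32 frames,
# 8 joints, effect size 1.0, noise sd 0.1, seed 0
SEPARABLE = dict(
    n_joints=8, frames=32, n_classes=4, samples_per_class=40,
    effect_size=1.0, noise_sd=0.1, seed=0,
)

# overlapping adjacent classes for the ordinal-loss comparison; smaller
# problem size so the paired 5-seed grid stays cheap
OVERLAPPING = dict(
    n_joints=8, frames=24, n_classes=4, samples_per_class=16,
    effect_size=0.4, noise_sd=0.3,
)

# fixed-length training: attention localization keeps developing after
# classification accuracy saturates, so no early stopping
LEARNABILITY_RUN = dict(epochs=100, eval_every=10)
OVERLAP_RUN = dict(epochs=60, eval_every=30)


def tiny_model_config(**overrides) -> ModelConfig:
    """A minimal architecture for fast pipeline-mechanics tests."""
    cfg = dict(fe_channels=[4, 8], mid_channels=8, n_head_blocks=1,
               node_hidden=4, edge_dim=2, kernel_size=3, dropout=0.0)
    cfg.update(overrides)
    return ModelConfig(**cfg)


@pytest.fixture(scope="session")
def topology8():
    return make_topology(8)


@pytest.fixture(scope="session")
def separable_dataset():
    cfg = SynthConfig(**SEPARABLE)
    return cfg, generate_dataset(cfg)


@pytest.fixture(scope="session")
def learnability_runs(separable_dataset, topology8):
    """Full-model training on the separable dataset, three seeds."""
    cfg, samples = separable_dataset
    runs = {}
    for seed in (0, 1, 2):
        runs[seed] = train(
            samples, topology8,
            ModelConfig(variant="pm", seed=seed),
            RunConfig(seed=seed, **LEARNABILITY_RUN),
        )
    return cfg, runs


@pytest.fixture(scope="session")
def ordinal_comparison(topology8):
    """Paired test MAE of the full model with and without the ordinal
    loss term on overlapping classes, five seeds."""
    results = {"with": [], "without": []}
    for seed in range(5):
        samples = generate_dataset(SynthConfig(seed=seed, **OVERLAPPING))
        for key, ordinal in (("with", True), ("without", False)):
            res = train(
                samples, topology8,
                ModelConfig(variant="pm", seed=seed),
                RunConfig(seed=seed, ordinal_loss=ordinal, **OVERLAP_RUN),
            )
            results[key].append(res.final_test.mae)
    return {k: np.array(v) for k, v in results.items()}
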