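"""Shared fixtures.

Heavy artifacts (the study-scale dataset and the trained surrogates) are
session-scoped so the acceptance-style tests share one generation/training
run instead of repeating it.
"""

from __future__ import annotations

import numpy as np
import pytest

from needleflex.beam_fea import NeedleSpec
from needleflex.dataset import generate_dataset
from needleflex.surrogate import train_ffnn, train_mlp, train_ols

#: Conditions for the scaled-down study: 1000 training / 2000 validation
#: insertions, FFNN at learning rate 0.005, Fourier scale 0.2, 500 epochs.
STUDY_SEED = 20260101
FULL_N_TRAIN = 1000
FULL_N_VAL = 2000
FFNN_LR = 0.005
FFNN_SCALE = 0.2
FFNN_EPOCHS = 500

#: Smaller common dataset for multi-seed robustness checks.
SMALL_N_TRAIN = 200
SMALL_N_VAL = 400


@pytest.fixture(scope="session")
def needle() -> NeedleSpec:
    return NeedleSpec()


@pytest.fixture(scope="session")
def tiny_split():
    """A few trajectories for fast unit-level checks."""
    return generate_dataset(3, 3, seed=11)


@pytest.fixture(scope="session")
def full_split():
    """Scaled-down study dataset: 1000 train / 2000 validation insertions."""
    return generate_dataset(FULL_N_TRAIN, FULL_N_VAL, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def full_ols(full_split):
    return train_ols(full_split.train)


@pytest.fixture(scope="session")
def full_mlp(full_split):
    return train_mlp(full_split.train, seed=0)


@pytest.fixture(scope="session")
def full_ffnn(full_split):
    return train_ffnn(
        full_split.train, learning_rate=FFNN_LR, scale=FFNN_SCALE, seed=0, epochs=FFNN_EPOCHS
    )


@pytest.fixture(scope="session")
def small_split():
    """Common scaled-down dataset for seed-robustness assertions."""
    return generate_dataset(SMALL_N_TRAIN, SMALL_N_VAL, seed=STUDY_SEED + 1)
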