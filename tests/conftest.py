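"""Shared fixtures: small, fast synthetic datasets and a tiny trained model.

Unit tests run on reduced problem sizes (few images, shallow cascades,
tens of trees); the full-scale protocols live in test_acceptance.py.
"""

import numpy as np
import pytest

from cephalo import GeneratorConfig, TrainConfig, sample_dataset, split_dataset, train

# mild variation so tiny training sets suffice for the unit-test properties
SMALL_GEN = GeneratorConfig(
    n_images=30, image_size=128, seed=101,
    placement_jitter=4.0, scale_jitter=0.03, rotation_jitter=2.0,
    shape_jitter=1.5, blur_sigma=0.8, noise_sd=4.0, margin=6,
)

SMALL_TRAIN = TrainConfig(
    nu=0.2, cascade_depth=6, tree_depth=1, oversampling=5,
    trees_per_stage=30, feature_pool_size=150, seed=202,
)


@pytest.fixture(scope="session")
def small_dataset():
    return sample_dataset(SMALL_GEN)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return split_dataset(small_dataset, 0.7, seed=7)


@pytest.fixture(scope="session")
def small_model(small_split):
    train_set, _ = small_split
    return train(train_set, SMALL_TRAIN)
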