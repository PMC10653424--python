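"""Shared fixtures: small synthetic datasets and tiny toy models.

The expensive trained-model fixtures live in test_acceptance.py (session
scoped there) so that unit-test runs stay fast.
"""

import numpy as np
import pandas as pd
import pytest

from funprose import ModelConfig, build_model, simulate


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset for plumbing tests (not for learning)."""
    dataset, truth = simulate(n_genes=40, n_tfs=6, n_conditions=12,
                              n_motifs=3, plant_prob=0.3, noise_sd=0.5,
                              length=200, seed=11)
    return dataset, truth


@pytest.fixture(scope="session")
def tiny_config():
    """Model config scaled to the 200-bp tiny dataset."""
    return ModelConfig.small(promoter_length=200, pool1=6, conv2_len=5,
                             pool2=4, conv1_kernels=8, conv2_kernels=8,
                             tf_hidden=16, head_sizes=(16, 8, 4),
                             max_epochs=3)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset, tiny_config):
    dataset, _ = tiny_dataset
    return build_model(tiny_config, n_tfs=len(dataset.tf_ids), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_expression():
    """4 samples / 2 conditions FPKM table with hand-checkable values."""
    return pd.DataFrame(
        {"s1": [2.0, 0.0, 5.0], "s2": [4.0, 0.0, 7.0],
         "s3": [1.0, 1.0, 9.0], "s4": [3.0, 3.0, 11.0]},
        index=["g1", "g2", "g3"])


@pytest.fixture()
def toy_replicate_map():
    return {"s1": "condA", "s2": "condA", "s3": "condB", "s4": "condB"}
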