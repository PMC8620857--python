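"""Shared fixtures: synthetic datasets and trained models.

The full parameter-recovery model (300 molecules, 100 epochs) takes a few
minutes to train, so it is session-scoped and shared between the attribution
tests and the acceptance suite.  Fast unit tests use a tiny model instead.
"""

from __future__ import annotations

import warnings

import pytest

from mmrt import MPNNConfig, parse_smiles, split_dataset, train
from mmrt.synthetic import SyntheticSpec, generate_molecules

RECOVERY_SEED = 11


@pytest.fixture(scope="session")
def synthetic_df():
    return generate_molecules(SyntheticSpec(n_molecules=300, seed=RECOVERY_SEED))

@pytest.fixture(scope="session")
def synthetic_graphs(synthetic_df):
    return [
        parse_smiles(s, name=n) for s, n in zip(synthetic_df.smiles, synthetic_df.name)
    ]


@pytest.fixture(scope="session")
def synthetic_split(synthetic_df):
    return split_dataset(len(synthetic_df), 0.8, seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def recovery_model(synthetic_df, synthetic_graphs, synthetic_split):
    """MPNN trained on the 318-molecule training portion of the synthetic
    set, full 100-epoch protocol."""
    dataset = list(zip(synthetic_graphs, synthetic_df.rt_min))
    trainset = [dataset[i] for i in synthetic_split.train]
    return train(trainset, MPNNConfig(hidden_dim=64, epochs=100, batch_size=64, seed=RECOVERY_SEED))


@pytest.fixture(scope="session")
def tiny_model():
    """Small, quickly trained model for plumbing tests (serialization,
    attribution identities, CLI)."""
    smiles = ["CCO", "CCC", "CCN", "CCCO", "CC(C)O", "CCCC", "CCCN", "CCOC"]
    rts = [5.0, 8.0, 3.0, 12.0, 9.0, 15.0, 4.0, 11.0]
    dataset = [(parse_smiles(s), rt) for s, rt in zip(smiles, rts)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train(dataset, MPNNConfig(hidden_dim=32, epochs=5, batch_size=8, seed=7))
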