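import logging

import numpy as np
import pytest

from lpiboost.deep import DeepGBDTClassifier
from lpiboost.io import InteractionDataset
from lpiboost.synthetic import SyntheticSpec, generate_dataset

logging.getLogger("lpiboost").setLevel(logging.ERROR)

NT = "ACGT"
AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_nt(rng, n):
    return "".join(rng.choice(list(NT), size=n))


def random_aa(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def tiny_classifier(**kw):
    """A desk-scale deep model for fast unit tests."""
    defaults = dict(hidden_dims=(4, 4), n_epochs=2, n_rounds=2,
                    num_boost_round=2, max_depth=3, random_state=0)
    defaults.update(kw)
    return DeepGBDTClassifier(**defaults)


@pytest.fixture
def two_cluster_data(rng):
    n = 120
    X = np.vstack([rng.normal(-1.0, 0.6, (n // 2, 3)),
                   rng.normal(1.0, 0.6, (n // 2, 3))])
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    perm = rng.permutation(n)
    return X[perm], y[perm]


@pytest.fixture(scope="session")
def small_synthetic():
    """A small planted-motif dataset shared across evaluation tests."""
    spec = SyntheticSpec(n_lncrna=40, n_protein=12,
                         lncrna_length=(60, 90), protein_length=(50, 70))
    return generate_dataset(spec, seed=7)


@pytest.fixture
def grid_dataset():
    """A fixed 5x4 interaction grid."""
    Y = np.zeros((5, 4), dtype=int)
    Y[[0, 1, 2, 4], [0, 1, 3, 2]] = 1
    return InteractionDataset([f"l{i}" for i in range(5)],
                              [f"p{j}" for j in range(4)], Y)
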