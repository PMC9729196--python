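import numpy as np
import pytest

from nbpoly.models import ModelSpec, train_model
from nbpoly.numbering import FrameConfig
from nbpoly.synthetic import SyntheticConfig, generate_pools


@pytest.fixture(scope="session")
def frame_config():
    return FrameConfig()


@pytest.fixture(scope="session")
def small_pools():
    """Small planted-signal pools shared across tests (seeded, deterministic)."""
    return generate_pools(SyntheticConfig(n_per_class=400, seed=101))


@pytest.fixture(scope="session")
def lr_suite(small_pools):
    """One-hot and k-mer logistic regressions trained on the small pools."""
    return {
        kind: train_model(ModelSpec(kind, seed=0), small_pools.low, small_pools.high)
        for kind in ("onehot_lr", "kmer_lr")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
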