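import numpy as np
import pytest

import triofactor as tf


@pytest.fixture(scope="session")
def bold_config():
    """Calibrated four-factor generating configuration, modest n."""
    return tf.default_config(n_trios=4000, seed=101)


@pytest.fixture(scope="session")
def bold_dataset(bold_config):
    return tf.simulate_trios(bold_config)


@pytest.fixture(scope="session")
def big_dataset():
    """Large panel under random mating / no selection (moment oracles)."""
    cfg = tf.default_config(n_trios=200_000, seed=7)
    return cfg, tf.simulate_trios(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def single_factor_config(n_trios=50_000, seed=0, **overrides):
    """Six-trait single-factor generator used by recovery tests."""
    lam = np.array([[0.7], [0.6], [0.5], [0.4], [0.3], [0.2]])
    traits = tuple(f"T{i+1}" for i in range(6))
    kw = dict(loadings=lam, n_trios=n_trios, seed=seed, trait_labels=traits)
    kw.update(overrides)
    return tf.GenerativeConfig(**kw)
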