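import numpy as np
import pytest

from csdp import CSDPClassifier, NetworkConfig, init_params, make_synthetic_dataset

# Desk-scale study conditions: a 2-class 12x12 templated set with 5% pixel
# flip noise, and a [144, 64, 32] circuit. The trace increment and goodness
# threshold are scaled to this width (gamma=0.5, theta_z=1.0: the goodness
# decision boundary sits at 4 concurrently active neurons, reachable under
# the homeostatic spike constraint); all other constants are the reference
# defaults.
SANITY_DATA = dict(n_classes=2, n_per_class=100, side=12, noise=0.05, rng_seed=7)
SANITY_MODEL = dict(
    hidden_layer_sizes=(64, 32), n_epochs=10, batch_size=20,
    gamma=0.5, theta_z=1.0, t_window=90.0, random_state=11,
)


@pytest.fixture(scope="session")
def sanity_dataset():
    return make_synthetic_dataset(**SANITY_DATA)


@pytest.fixture(scope="session")
def trained_supervised(sanity_dataset):
    est = CSDPClassifier(supervised=True, **SANITY_MODEL)
    est.fit(sanity_dataset.images, sanity_dataset.labels)
    return est


@pytest.fixture(scope="session")
def trained_unsupervised(sanity_dataset):
    est = CSDPClassifier(supervised=False, **SANITY_MODEL)
    est.fit(sanity_dataset.images, sanity_dataset.labels)
    return est


@pytest.fixture
def tiny_cfg():
    return NetworkConfig(layer_sizes=(6, 5, 4, 3), n_classes=2,
                         supervised=True, gamma=0.5, theta_z=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_config(rng, supervised=True, max_width=8, n_hidden=None):
    """A random small configuration for oracle-equivalence instances."""
    if n_hidden is None:
        n_hidden = int(rng.integers(1, 4))
    sizes = tuple(int(rng.integers(2, max_width + 1)) for _ in range(n_hidden + 1))
    return NetworkConfig(
        layer_sizes=sizes,
        n_classes=int(rng.integers(2, 5)),
        supervised=supervised,
        dt=3.0,
        tau_m=float(rng.uniform(6.0, 40.0)),
        tau_tr=float(rng.uniform(3.0, 12.0)),
        gamma=float(rng.uniform(0.05, 0.8)),
        theta_z=float(rng.uniform(0.2, 10.0)),
        lambda_v=0.001,
        lambda_d=5e-5,
        r_e=float(rng.uniform(0.5, 1.5)),
        r_i=float(rng.uniform(0.5, 1.5)),
        t_window=90.0,
        v_thr_init=float(rng.uniform(0.2, 1.0)),
    )


def random_instance(rng, **kwargs):
    """(cfg, params, sensory drive) for a random small network."""
    cfg = random_config(rng, **kwargs)
    params = init_params(cfg, rng)
    return cfg, params
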