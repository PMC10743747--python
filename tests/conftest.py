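import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lvclust import Cluster, DistractorSpec, PhantomConfig, generate_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_cluster(coords, labels, shape=(64, 64)):
    return Cluster(np.asarray(coords), np.asarray(labels), shape)


def random_cluster(rng, shape=(40, 40), max_size=12):
    n = int(rng.integers(1, max_size + 1))
    flat = rng.choice(shape[0] * shape[1], size=n, replace=False)
    coords = np.column_stack(np.unravel_index(flat, shape))
    labels = rng.integers(1, 4, size=n)
    return Cluster(coords, labels, shape)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_phantom_cfg():
    """64 px frame, 5 slices — fast enough for per-test regeneration."""
    return PhantomConfig(image_size=64, n_slices=5, lv_outer_radius=20.0,
                         el_thickness=6.0, seed=11)


@pytest.fixture(scope="session")
def clean_phantom(small_phantom_cfg):
    return generate_phantom(small_phantom_cfg)


@pytest.fixture(scope="session")
def distractor_phantom():
    """Phantom with a far right-ventricle mimic on every slice."""
    cfg = PhantomConfig(
        image_size=96, n_slices=6, lv_center=(48, 34), lv_outer_radius=22.0,
        el_thickness=6.0, seed=5,
        distractors=(DistractorSpec("rv_mimic", center=(48, 80), radius=9, jitter=2),),
    )
    return generate_phantom(cfg)
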