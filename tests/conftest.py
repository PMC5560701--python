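import numpy as np
import pytest

from freshmap import features, scene_sim


@pytest.fixture(scope="session")
def small_scene():
    """64x64 scene, 12 dates, moderate noise and clouds."""
    cfg = scene_sim.SceneConfig(
        width=64, height=64, n_dates=12, cloud_fraction=0.2, noise_sd=0.02, seed=7
    )
    return scene_sim.generate_scene(cfg)


@pytest.fixture(scope="session")
def small_features(small_scene):
    return features.extract_features(small_scene.stack)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_stack(rng, h=16, w=16, t=10, cloud=0.2):
    """Random but valid observation stack for oracle comparisons."""
    refl = rng.uniform(0.0, 1.0, (h, w, t, 4))
    valid = rng.random((h, w, t)) >= cloud
    from freshmap.types import ObservationStack

    return ObservationStack(refl, valid, np.arange(t))
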