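import numpy as np
import pytest

from madet.pipeline import run_synthetic_experiment
from madet.preprocess import FundusImage
from madet.synthetic import SceneConfig, generate_scene

# master seed of the scaled-down end-to-end study
E2E_SEED = 0


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 128x128 scene with 4 lesions."""
    return generate_scene(
        SceneConfig(height=128, width=128, n_lesions=4, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_fundus(rng, h, w, image_id="img"):
    """Uniform-noise RGB image helper for oracle tests."""
    return FundusImage(
        rng.uniform(0, 255, (h, w, 3)).astype(np.float32), image_id=image_id
    )


@pytest.fixture(scope="session")
def e2e_result():
    """The scaled-down end-to-end study: 20 train + 10 test scenes,
    256x256, 8 lesions each, 25x25 patches, 5 epochs per stage."""
    return run_synthetic_experiment(seed=E2E_SEED)
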