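import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message=".*puncta clipped.*")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One modest ground-truthed scene shared by read-only tests."""
    from arraytomo.synthetic import SceneParams, generate_scene

    params = SceneParams(field_x=20.0, field_y=20.0, n_sections=16, seed=42)
    return generate_scene(params)


@pytest.fixture(scope="session")
def noise_free_optics():
    from arraytomo.synthetic import OpticsParams

    return OpticsParams(
        psf_sigma_xy=0.1,
        gaussian_noise_sd=0.0,
        photon_noise=False,
        jitter_translation_max=0.0,
        jitter_rotation_max=0.0,
        speckle_rate=0.0,
        bit_depth=None,
    )
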