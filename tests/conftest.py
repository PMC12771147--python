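import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20251009)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Default calibration scene rendered without pixel noise."""
    from diaquant import imaging, synthgen

    spec = synthgen.default_calibration_scene(noise_sd=0.0, seed=0)
    img, truth = synthgen.render_scene(spec)
    rois = synthgen.scene_rois(spec)
    signals = imaging.signals_table(img, rois)
    return spec, img, truth, rois, signals


@pytest.fixture(scope="session")
def noisy_scene():
    """Default calibration scene at the standard pixel noise (sd = 2)."""
    from diaquant import imaging, synthgen

    spec = synthgen.default_calibration_scene(noise_sd=2.0, seed=42)
    img, truth = synthgen.render_scene(spec)
    rois = synthgen.scene_rois(spec)
    signals = imaging.signals_table(img, rois)
    return spec, img, truth, rois, signals
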