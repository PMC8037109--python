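import pytest

from imurehab import synth
from imurehab.io import derive_signals
from imurehab.segmentation import SegmenterParams, build_template


@pytest.fixture()
def noise_free_config():
    """A sensor-noise-free, offset-free generator config (deterministic
    geometry aside from the duration/amplitude draws)."""
    return synth.CohortConfig(
        noise_sd_accel=0.0, noise_sd_gyro=0.0, orientation_sd=0.0, seed=5
    )


@pytest.fixture()
def noise_free_session(noise_free_config):
    rec, ann = synth.generate_session(noise_free_config, "S01", "HS", 0)
    return rec, ann


@pytest.fixture()
def noise_free_signals(noise_free_session):
    rec, ann = noise_free_session
    return derive_signals(rec), ann


@pytest.fixture()
def hs_template(noise_free_signals):
    sig, ann = noise_free_signals
    params = SegmenterParams()
    reps = [sig.gyro_y[r.start:r.end] for r in ann]
    return build_template(reps, params, "HS")
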