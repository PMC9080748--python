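import warnings

import numpy as np
import pytest

from sidewinderkin import (SmoothConfig, TrialGroundTruth, WaveParams,
                           generate_trajectory, smooth_trial)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def slow_wave():
    """A slow steady sidewinding wave inside the smoothing passband."""
    return WaveParams(frequency_hz=0.3, wavelength_cm=20.0,
                      amplitude_cm=10.0, skew_deg=5.0, lift_height_cm=2.0,
                      duty=0.25, smooth_frac=0.04)


@pytest.fixture(scope="session")
def slow_trial(slow_wave):
    return TrialGroundTruth(wave=slow_wave, n_frames=4500, noise_sd_cm=0.0,
                            seed=11)


@pytest.fixture(scope="session")
def slow_tracks(slow_trial):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_trajectory(slow_trial)


@pytest.fixture(scope="session")
def slow_smoothed(slow_tracks):
    return smooth_trial(slow_tracks, SmoothConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
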