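import dataclasses

import numpy as np
import pytest

from osteochondral.containers import HistoImage
from osteochondral.synthetic import default_grade_profiles, generate_section


@pytest.fixture(scope="session")
def profiles():
    return default_grade_profiles()


@pytest.fixture(scope="session")
def clean_profile(profiles):
    """Grade-0 profile with all randomness switched off: flat layers."""
    return dataclasses.replace(
        profiles[0],
        uncalc_cart_sd=0.0,
        calc_cart_sd=0.0,
        plate_sd=0.0,
        roughness_amplitude=0.0,
        fenestra_rate=0.0,
    )


@pytest.fixture(scope="session")
def flat_section(clean_profile):
    """Noiseless, blur-free flat section at 2 um/px: exact geometry."""
    return generate_section(
        clean_profile, 128, 256, 2.0, seed=0, noise_sd=0.0, blur_sigma_px=0.0
    )


@pytest.fixture()
def step_image():
    """Two-level image: rows 0-5 dark (cartilage), rows 6-11 bright (bone)."""
    data = np.full((12, 12), 100.0)
    data[6:, :] = 200.0
    return HistoImage(data, pixel_size=1.0)
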