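import numpy as np
import pytest

from tbut.synthetic_data import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def easy_sim_config():
    """High-contrast, low-noise study conditions for learning experiments.

    Onsets are drawn well inside the open-eye span so every subtest has a
    true break-up time, spots are large and dark, and noise is mild -- the
    regime where a correctly implemented pipeline must recover the TBUT.
    """
    return SimConfig(
        image_size=64,
        fps=60.0,
        open_duration_s=(4.0, 6.0),
        onset_time_s=(0.5, 3.5),
        spot_growth_px_per_s=8.0,
        spot_base_radius_px=2.0,
        spot_contrast=0.7,
        noise_sd=0.02,
        seed=0,
    )


@pytest.fixture(scope="session")
def labels_only_config():
    """Cheap config for label-level tests (no rendering)."""
    return SimConfig(image_size=32, fps=60.0)
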