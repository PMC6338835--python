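import numpy as np
import pytest

from psfret import AcquisitionSpec, PhotophysicsModel, donor_alone_scene, tandem_dimer_scene


@pytest.fixture
def model():
    """Default Dronpa-like photophysics: k=1/s, 75x contrast, 8% bleed-through."""
    return PhotophysicsModel(k_d=1.0, contrast=75.0, d_true=0.08, q_rel=0.9)


@pytest.fixture
def acq():
    """100 frames at 50 ms, 500 e- initial per unit concentration."""
    return AcquisitionSpec(n_frames=100, frame_interval=0.05, photons_initial=500.0, seed=1234)


@pytest.fixture
def tandem():
    return tandem_dimer_scene(e_single=0.3)


@pytest.fixture
def donor_only():
    return donor_alone_scene()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
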