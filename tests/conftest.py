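import numpy as np
import pytest

from cohmap.synthetic import (make_cortical_sheet, make_twophoton_truth,
                              simulate_twophoton_session)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sheet7():
    """64 x 64 seven-area sheet with the default planted gradients."""
    return make_cortical_sheet(shape=(64, 64), n_areas=7, seed=1)


@pytest.fixture(scope="session")
def sheet2():
    return make_cortical_sheet(shape=(64, 64), n_areas=2, seed=1)


@pytest.fixture(scope="session")
def twophoton_session():
    """Small two-photon session with planted motion (shared across tests)."""
    truth = make_twophoton_truth(shape=(96, 96), n_cells=20, seed=3)
    return truth, simulate_twophoton_session(truth, seed=4)


@pytest.fixture(scope="session")
def twophoton_session_still():
    """Same field, no planted frame-to-frame motion."""
    truth = make_twophoton_truth(shape=(96, 96), n_cells=20, seed=3)
    return truth, simulate_twophoton_session(truth, seed=4, motion_amplitude_px=0)
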