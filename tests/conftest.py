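import numpy as np
import pytest
from hypothesis import settings

from pursuitkin.models import ControllerSpec
from pursuitkin.synthetic import SyntheticSpec, _generate_set

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

FRAME = 1.0 / 190.0

BP_HORIZONTAL = ControllerSpec(strategy="BP", kp=26.0, beta=0.0, dt1=2 * FRAME, plane="horizontal")
PN_HORIZONTAL = ControllerSpec(strategy="PN", N=1.8, dt2=0.026, plane="horizontal")


@pytest.fixture(scope="session")
def bp_chases_noisy():
    """20 spring-target chases generated by BP (kp=26, dt=2 frames), 5 mm noise."""
    return _generate_set(SyntheticSpec(controller=BP_HORIZONTAL, seed=1, noise_sd=0.005), 20)


@pytest.fixture(scope="session")
def pn_chases_noisy():
    """20 spring-target chases generated by PN (N=1.8, dt=26 ms), 5 mm noise."""
    return _generate_set(SyntheticSpec(controller=PN_HORIZONTAL, seed=1, noise_sd=0.005), 20)


@pytest.fixture(scope="session")
def default_chases_noisy():
    """20 chases with the fitted blowfly controllers (horizontal + vertical), 5 mm noise."""
    return _generate_set(SyntheticSpec(seed=1, noise_sd=0.005), 20)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def straight_track():
    """Simple straight-motion track: pursuer along +x, target ahead on +x."""
    from pursuitkin.track import PursuitTrack

    n = 10
    t = np.arange(n) * FRAME
    pur = np.column_stack([0.1 * np.arange(n) * FRAME * 190, np.zeros(n), np.zeros(n)])
    tar = np.column_stack([2.0 + np.zeros(n), np.zeros(n), np.zeros(n)])
    return PursuitTrack(t, pur, tar, chase_id="straight", frame_rate=190.0)
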