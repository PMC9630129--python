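import numpy as np
import pytest

from thetapop import LfpSignal, SimConfig, make_session, simulate_lfp
from thetapop.lfp import segment_theta


@pytest.fixture(scope="session")
def clean_theta_lfp():
    """Noise-free fixed-frequency 8-Hz LFP with its generating phase."""
    cfg = SimConfig(duration=30.0, noise_amp=0.0, theta_jitter=0.0, rng_seed=7)
    lfp, phase = simulate_lfp(cfg)
    return lfp, phase


@pytest.fixture(scope="session")
def jittered_lfp():
    """Realistic LFP (frequency wander + 1/f noise) with ground-truth phase."""
    cfg = SimConfig(duration=60.0, rng_seed=11)
    lfp, phase = simulate_lfp(cfg)
    return lfp, phase


@pytest.fixture(scope="session")
def clean_cycles(clean_theta_lfp):
    lfp, _ = clean_theta_lfp
    return segment_theta(lfp)


@pytest.fixture(scope="session")
def toy_activation_session():
    """Short activation-protocol session used by several analysis tests."""
    cfg = SimConfig(duration=60.0, protocol="activation", rng_seed=3)
    return make_session(cfg)


@pytest.fixture(scope="session")
def toy_silencing_session():
    """Short silencing-protocol session (a few 30-s pulses)."""
    cfg = SimConfig(duration=180.0, protocol="silencing", rng_seed=5)
    return make_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
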