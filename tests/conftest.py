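"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from fcrnet import SimulationConfig, generate_session, generate_session_with_truth


@pytest.fixture(scope="session")
def default_session():
    """Full-size default session (288 x 22 x 1000) at 6 dB."""
    return generate_session(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_session():
    """Desk-scale session: 4 classes, 12 trials/class, 8 channels, 2 s."""
    cfg = SimulationConfig(trials_per_class=12, n_channels=8,
                           trial_duration=2.0, snr_db=10.0, seed=7)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def session_with_truth():
    """Default-shape session plus its mixing-matrix ground truth."""
    return generate_session_with_truth(SimulationConfig(snr_db=6.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
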