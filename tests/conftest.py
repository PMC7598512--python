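import numpy as np
import pytest

from entrystate.synthetic_data import aligned_entry_state, default_profile


@pytest.fixture(scope="session")
def profile():
    """Reference male anthropometric profile (1.86 m, 78.9 kg)."""
    return default_profile()


@pytest.fixture(scope="session")
def female_profile():
    return default_profile(height=1.73, total_mass=65.6, sex="female")


@pytest.fixture
def rng():
    return np.random.default_rng(20231030)


@pytest.fixture
def typical_entry(profile):
    """A representative aligned entry state (regular start)."""
    return aligned_entry_state(
        profile, trunk_angle=-0.37, fingertip=(3.1, 0.0),
        com_velocity=(4.4, -3.1), angular_velocity=-2.0,
    )
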