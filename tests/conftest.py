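import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from segclock.oscillator import (
    OscillatorParams,
    damascus_like_params,
    solve_preset_pattern,
    wt_like_params,
)

TWO_PI = 2.0 * np.pi


@pytest.fixture(scope="session")
def wt_pattern():
    """Solved wildtype-like steady wave pattern (session-cached)."""
    return solve_preset_pattern(wt_like_params())


@pytest.fixture(scope="session")
def damascus_pattern():
    """Solved elevated-coupling steady wave pattern (session-cached)."""
    return solve_preset_pattern(damascus_like_params())


@pytest.fixture
def uncoupled_params():
    """Uncoupled chain with a linear frequency gradient and advection."""
    return OscillatorParams(
        n_cells=200, spacing_a=2.5, omega0=TWO_PI / 23.5,
        profile_shape="linear", advection_v=3.0, epsilon=0.0,
    )
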