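import numpy as np
import pytest

import trapscape as ts


@pytest.fixture(scope="session")
def three_state_spec():
    """Designed three-state ground truth: dG_NF=1.0, dG_FE=0.5 k_BT,
    saddles at 3.5 and 4.0 k_BT, 25 mV wells, A=0.9."""
    return ts.design_three_state_spec(
        delta_g_nf=1.0, delta_g_fe=0.5, barrier_nf=3.5, barrier_fe=3.0,
        well_sigma=0.025, prefactor_a=0.9, temperature=312.0)


@pytest.fixture(scope="session")
def two_state_spec():
    return ts.design_two_state_spec(delta_g=0.7, barrier=3.0,
                                    well_sigma=0.025, temperature=310.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
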