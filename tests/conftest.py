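import numpy as np
import pytest

from senolattice import InductionSpec, SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def null_params():
    """All transition probabilities zero, no induction: an absorbing all-R
    configuration."""
    return SimulationParams(
        dims=(10, 10),
        n_steps=20,
        p_bys=0.0,
        p_clr=0.0,
        p_new=0.0,
        induction_mode="none",
        seed=0,
    )


@pytest.fixture
def irradiation_params():
    """Reference in-vivo parameterisation, Bernoulli induction layer."""
    return SimulationParams(
        dims=(10, 10),
        n_steps=50,
        induction_mode="irradiation_day1",
        induction=InductionSpec(mode="bernoulli", p_ind=0.1),
        seed=1,
    )
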