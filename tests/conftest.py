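import pytest
from hypothesis import settings

import hepaflux as hf

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def baseline_scenario():
    """Recommended protein intake (71 g/day), liver without disease."""
    return hf.build_scenario(71.0, "normal")


@pytest.fixture(scope="session")
def baseline_traj(baseline_scenario):
    return hf.simulate(baseline_scenario)


@pytest.fixture(scope="session")
def baseline_ss(baseline_traj):
    return hf.detect_steady_state(baseline_traj)


@pytest.fixture(scope="session")
def glul_knockout_traj(baseline_scenario):
    return hf.simulate(baseline_scenario.with_kinetics(vmax_glul=0.0))


@pytest.fixture(scope="session")
def grid_df():
    """The full 3 diets x 3 liver conditions steady-state grid."""
    return hf.run_grid()


@pytest.fixture(scope="session")
def sensitivity_df():
    """+-50% perturbation of all seven kinetic parameters at (71 g, normal)."""
    return hf.sensitivity_analysis()
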