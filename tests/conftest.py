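import numpy as np
import pytest

import hemopkpd as hp


@pytest.fixture(scope="session")
def table1():
    return hp.table1_pd_params()


@pytest.fixture(scope="session")
def nominal_pk():
    return hp.nominal_pk_params()


@pytest.fixture(scope="session")
def baselines(table1):
    return hp.solve_baselines(table1)


@pytest.fixture(scope="session")
def arm_trajectories(table1, nominal_pk):
    """Fast-mode trajectories of all 9 study arms on an hourly grid."""
    out = {}
    for arm in hp.STUDY_ARMS:
        spec = hp.SimulationSpec(hp.build_study_arm(arm), nominal_pk, table1)
        out[arm] = hp.simulate(spec, mode="fast")
    return out


@pytest.fixture(scope="session")
def coupled_trajectories(table1, nominal_pk):
    """Reference coupled-ODE trajectories of all 9 study arms."""
    out = {}
    for arm in hp.STUDY_ARMS:
        spec = hp.SimulationSpec(hp.build_study_arm(arm), nominal_pk, table1)
        out[arm] = hp.simulate(spec, mode="coupled")
    return out
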