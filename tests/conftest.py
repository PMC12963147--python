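import numpy as np
import pytest

import reflectsim as rs


@pytest.fixture(scope="session")
def vent_long():
    """Volume control, IF 12 L/min: 2.5 s flow, 0.5 s pause, 3 s expiration."""
    return rs.VentilationSettings(inspiratory_flow_lpm=12.0)


@pytest.fixture(scope="session")
def vent_short():
    """Volume control, IF 60 L/min: 0.5 s flow, 2.5 s pause."""
    return rs.VentilationSettings(inspiratory_flow_lpm=60.0)


@pytest.fixture(scope="session")
def iso():
    return rs.AgentSpec.isoflurane()


@pytest.fixture(scope="session")
def sevo():
    return rs.AgentSpec.sevoflurane()


@pytest.fixture(scope="session")
def staircase():
    return rs.build_staircase_schedule()


@pytest.fixture(scope="session")
def full_sim_long(vent_long, iso, staircase):
    """One full 160-min isoflurane experiment at long inspiratory-flow time."""
    return rs.simulate_experiment(vent_long, iso, staircase, seed=0)


@pytest.fixture(scope="session")
def full_breaths_long(full_sim_long):
    return rs.analyze_trace(full_sim_long.trace)


def make_flat_trace(n_samples=60, run_start=10, run_len=30, agent_value=1.0, co2_plateau=40.0):
    """Hand-built single-breath trace: one supra-threshold CO2 run."""
    co2 = np.zeros(n_samples)
    co2[run_start : run_start + run_len] = co2_plateau
    agent = np.full(n_samples, agent_value)
    return rs.GasTrace(agent_volpct=agent, co2_mmhg=co2, sample_period_s=0.1)
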