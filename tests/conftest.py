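"""Shared fixtures: deterministic synthetic trajectories and simulations."""

import numpy as np
import pandas as pd
import pytest

import tomsugar as ts
from tomsugar.core_model import CarbonPools, RateSchedule, daa_to_hours
from tomsugar.units import observation_to_concentrations


@pytest.fixture(scope="session")
def constants():
    return ts.ModelConstants()


@pytest.fixture(scope="session")
def gen_config():
    return ts.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def control_truth(gen_config):
    return ts.generate_allocation("CK", "K0", gen_config)


@pytest.fixture(scope="session")
def control_observations(control_truth, gen_config):
    return ts.sample_observations(control_truth, gen_config)


@pytest.fixture(scope="session")
def environment(gen_config):
    return ts.generate_temperature(gen_config)


@pytest.fixture(scope="session")
def control_growth(gen_config):
    return ts.generate_growth("CK", "K0", gen_config)


@pytest.fixture(scope="session")
def known_rate_simulation(control_growth, environment):
    """Forward run with known decaying-exponential rate schedules.

    Returns (simulation, schedule grid DAA, true k3, true k5m, k5).
    """
    k5 = ts.ModelConstants().k5
    daa = np.arange(30.0, 73.01, 0.5)
    k3 = 0.6 * np.exp(-(daa - 30.0) / 12.0)
    k5m = 0.65 * np.exp(-(daa - 30.0) / 9.0)
    sched = RateSchedule(daa, k3, k5m, k5_per_day=k5)
    sim = ts.simulate_forward(
        CarbonPools(0.05, 0.09, 0.42), control_growth, environment, sched, step=0.5
    )
    return sim, daa, k3, k5m, k5


def observations_from_simulation(sim, growth, sample_daa, noise_cv, seed, n_reps=3):
    """Sample a forward simulation back into an assay-style table."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def noise():
        return rng.lognormal(-sigma**2 / 2.0, sigma) if noise_cv > 0 else 1.0

    rows = []
    for rep in range(n_reps):
        for a in sample_daa:
            t = daa_to_hours(a)
            c_sol = float(np.interp(t, sim.t_h, sim.C_sol))
            c_sta = float(np.interp(t, sim.t_h, sim.C_sta))
            c_str = float(np.interp(t, sim.t_h, sim.C_str))
            fw = float(growth.fw_at(t))
            dw = (c_sol + c_sta + c_str) / ts.ModelConstants().c_DW
            ssc, stc = observation_to_concentrations(CarbonPools(c_sol, c_sta, c_str), fw)
            rows.append(
                {
                    "treatment": "CK",
                    "water": "CK",
                    "potassium": "K0",
                    "replicate": rep + 1,
                    "DAA": a,
                    "FW": fw * noise(),
                    "DW": dw * noise(),
                    "SSC": ssc * noise(),
                    "STC": stc * noise(),
                }
            )
    return pd.DataFrame(rows)
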