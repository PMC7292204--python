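"""Smoothing, derivative estimation, and rate recovery."""

import numpy as np
import pandas as pd
import pytest

import tomsugar as ts
from tomsugar.core_model import daa_to_hours
from tomsugar.inversion import (
    EstimationError,
    _simulation_sse,
    estimate_k3,
    estimate_k5m,
    estimate_supply_flux,
    fit_growth_from_observations,
    interior_window,
    local_polynomial_smooth,
    smooth_pools,
)
from tomsugar.units import pools_table

from conftest import observations_from_simulation


class TestLocalPolynomial:
    def test_reproduces_linear_exactly(self):
        x = np.linspace(0, 10, 30)
        grid = np.linspace(0.5, 9.5, 15)
        val, der = local_polynomial_smooth(x, 2.0 * x, grid, bandwidth=0.4)
        assert np.allclose(val, 2.0 * grid, atol=1e-9)
        assert np.allclose(der, 2.0, atol=1e-9)

    def test_reproduces_quadratic_exactly(self):
        x = np.linspace(0, 10, 30)
        grid = np.linspace(0.0, 10.0, 21)
        val, der = local_polynomial_smooth(x, x**2, grid, bandwidth=0.4)
        assert np.allclose(val, grid**2, atol=1e-8)
        assert np.allclose(der, 2.0 * grid, atol=1e-8)

    def test_noisy_sigmoid_derivative_within_10pct_of_peak(self):
        """Derivative error on a noisy sigmoid stays under 10% of the peak rate."""
        rng = np.random.default_rng(42)
        x = np.repeat(np.linspace(0, 40, 17), 3)
        true = 5.0 / (1.0 + np.exp(-(x - 20.0) / 5.0))
        y = true * rng.lognormal(-0.05**2 / 2, 0.05, size=x.size)
        grid = np.linspace(4, 36, 33)
        _, der = local_polynomial_smooth(x, y, grid, bandwidth=0.25)
        true_der = 5.0 / 5.0 * np.exp(-(grid - 20) / 5) / (1 + np.exp(-(grid - 20) / 5)) ** 2
        peak = 5.0 / (4 * 5.0)  # max of the logistic derivative
        assert np.max(np.abs(der - true_der)) <= 0.10 * peak

    def test_too_few_points_raises(self):
        with pytest.raises(EstimationError):
            local_polynomial_smooth(np.array([1.0, 2.0, 3.0]), np.ones(3), np.array([2.0]), 0.5)


class TestRateFormulas:
    def _smoothed(self, c_sol, c_sta, d_sta, d_str):
        grid = np.array([40.0, 50.0])
        one = np.ones(2)
        return ts.SmoothedTrajectory(
            daa=grid, C_sol=c_sol * one, C_sta=c_sta * one, C_str=one,
            dC_sol=0 * one, dC_sta=d_sta * one, dC_str=d_str * one, bandwidth=0.6,
        )

    def test_k3_zero_when_structural_constant(self):
        k3, raw, flags = estimate_k3(self._smoothed(0.5, 0.1, 0.0, 0.0))
        assert np.allclose(k3, 0.0) and not flags.any()

    def test_k3_hand_arithmetic(self):
        k3, _, _ = estimate_k3(self._smoothed(0.5, 0.1, 0.0, 0.02))
        assert np.allclose(k3, 0.04)

    def test_k5m_constant_starch(self):
        """Zero starch derivative leaves only the breakdown-replacement term."""
        sm = self._smoothed(0.5, 0.2, 0.0, 0.0)
        k5m, _, _ = estimate_k5m(sm, k5=0.3)
        assert np.allclose(k5m, 0.3 * 0.2 / 0.5)

    def test_k5m_zero_without_starch(self):
        k5m, _, flags = estimate_k5m(self._smoothed(0.5, 0.0, 0.0, 0.0), k5=0.3)
        assert np.allclose(k5m, 0.0)

    def test_low_csol_flagged(self):
        k3, raw, flags = estimate_k3(self._smoothed(0.0, 0.1, 0.0, 0.02))
        assert flags.all() and np.isnan(k3).all()

    def test_negative_estimate_floored_but_raw_kept(self):
        k3, raw, flags = estimate_k3(self._smoothed(0.5, 0.1, 0.0, -0.02))
        assert np.allclose(k3, 0.0) and np.allclose(raw, -0.04) and flags.all()


class TestSupplyFlux:
    def test_flat_dw_is_maintenance_only(self):
        t = np.array([0.0, 100.0])
        growth = ts.GrowthCurve(t, [1.0, 1.0], [10.0, 10.0], [0.0, 0.0])
        env = ts.EnvironmentSeries(t, [20.0, 20.0])
        flux = estimate_supply_flux(growth, env)
        assert np.allclose(flux, 0.000168)

    def test_integrated_supply_minus_respiration_is_structural_gain(
        self, known_rate_simulation
    ):
        sim = known_rate_simulation[0]
        c_dw_gain = (sim.C_sol[-1] + sim.C_sta[-1] + sim.C_str[-1]) - (
            sim.C_sol[0] + sim.C_sta[0] + sim.C_str[0]
        )
        assert sim.C_sup[-1] - sim.C_rep[-1] == pytest.approx(c_dw_gain, abs=1e-9)


class TestRoundtripRecovery:
    def test_noiseless_dense_recovery_within_2pct(self, known_rate_simulation):
        """Forward-simulate with known rates, sample densely, invert."""
        sim, daa, k3_true, k5m_true, k5 = known_rate_simulation
        sample = np.arange(30.0, 73.01, 1.0)
        pools = pd.DataFrame(
            {
                "DAA": sample,
                "C_sol": np.interp(daa_to_hours(sample), sim.t_h, sim.C_sol),
                "C_sta": np.interp(daa_to_hours(sample), sim.t_h, sim.C_sta),
                "C_str": np.interp(daa_to_hours(sample), sim.t_h, sim.C_str),
            }
        )
        sm = smooth_pools(pools, bandwidth=0.15, grid_step=1.0)
        k3_est, _, _ = estimate_k3(sm)
        k5m_est, _, _ = estimate_k5m(sm, k5)
        lo, hi = interior_window(sample[0], sample[-1])
        m = (sm.daa >= lo) & (sm.daa <= hi)
        k3_ref = np.interp(sm.daa[m], daa, k3_true)
        k5m_ref = np.interp(sm.daa[m], daa, k5m_true)
        assert np.max(np.abs(k3_est[m] - k3_ref) / k3_ref) <= 0.02
        assert np.max(np.abs(k5m_est[m] - k5m_ref) / k5m_ref) <= 0.02

    def test_noisy_sparse_recovery_median_within_25pct(self, gen_config):
        """Generator pipeline: median recovered rates across 50 seeds."""
        ratios_k3, ratios_k5m = [], []
        for seed in range(50):
            cfg = gen_config.with_(seed=seed)
            truth = ts.generate_allocation("CK", "K0", cfg)
            obs = ts.sample_observations(truth, cfg)
            sm = smooth_pools(pools_table(obs), bandwidth=0.6, grid_step=1.0)
            k3_est, _, _ = estimate_k3(sm)
            k5m_est, _, _ = estimate_k5m(sm, ts.ModelConstants().k5)
            lo, hi = interior_window(34.0, 73.0)
            m = (sm.daa >= lo) & (sm.daa <= hi)
            ratios_k3.append(k3_est[m] / np.interp(sm.daa[m], truth.daa, truth.k3))
            ratios_k5m.append(k5m_est[m] / np.interp(sm.daa[m], truth.daa, truth.k5m))
        med3 = np.median(np.array(ratios_k3), axis=0)
        med5 = np.median(np.array(ratios_k5m), axis=0)
        assert np.all(np.abs(med3 - 1.0) <= 0.25)
        assert np.all(np.abs(med5 - 1.0) <= 0.25)

    def test_rates_decay_from_early_peak_to_near_zero(self, control_truth, gen_config):
        """On default trajectories the estimated rates peak first, vanish last."""
        obs = ts.sample_observations(control_truth, gen_config)
        sm = smooth_pools(pools_table(obs), bandwidth=0.6, grid_step=1.0)
        k3_est, _, _ = estimate_k3(sm)
        k5m_est, _, _ = estimate_k5m(sm, ts.ModelConstants().k5)
        # peak sits at the start of the window (within noise wobble) and
        # both rates have collapsed by the final age
        n = len(sm.daa)
        assert np.argmax(k3_est) <= 0.15 * n and np.argmax(k5m_est) <= 0.15 * n
        assert k3_est[0] >= 0.85 * max(k3_est) and k5m_est[0] >= 0.85 * max(k5m_est)
        assert k3_est[-1] < 0.05 * max(k3_est)
        assert k5m_est[-1] < 0.05 * max(k5m_est)


class TestCalibrateK5:
    def test_default_constant(self):
        assert ts.ModelConstants().k5 == 0.296517337

    def test_one_sided_identification(self, known_rate_simulation, control_growth, environment):
        """Candidates far below the generating k5 fit strictly worse; above, flat."""
        sim = known_rate_simulation[0]
        k5_true = known_rate_simulation[4]
        obs = observations_from_simulation(sim, control_growth, np.arange(30, 73.01, 2.0), 0.0, 0)
        pools = pools_table(obs)
        sm = smooth_pools(pools, bandwidth=0.2)
        gf = fit_growth_from_observations(obs, bandwidth=0.2)
        const = ts.ModelConstants()
        sse_low = _simulation_sse(0.05, sm, gf, environment, const, pools, 2.0)
        sse_true = _simulation_sse(k5_true, sm, gf, environment, const, pools, 2.0)
        sse_high = _simulation_sse(0.8, sm, gf, environment, const, pools, 2.0)
        assert sse_low > 1.2 * sse_true
        assert sse_high == pytest.approx(sse_true, rel=0.05)

    def test_noiseless_knee_recovery(self, known_rate_simulation, control_growth, environment):
        sim = known_rate_simulation[0]
        k5_true = known_rate_simulation[4]
        obs = observations_from_simulation(sim, control_growth, np.arange(30, 73.01, 2.0), 0.0, 0)
        k5_hat, flat = ts.calibrate_k5(obs, environment, bandwidth=0.2)
        assert not flat
        assert abs(k5_hat - k5_true) / k5_true <= 0.15

    def test_flat_objective_flagged_when_starch_absent(
        self, known_rate_simulation, control_growth, environment
    ):
        sim = known_rate_simulation[0]
        obs = observations_from_simulation(sim, control_growth, np.arange(30, 73.01, 2.0), 0.0, 0)
        obs["STC"] = 0.0
        k5_hat, flat = ts.calibrate_k5(obs, environment, interval=(0.02, 1.0), n_scan=5)
        assert flat and k5_hat == pytest.approx(0.51)
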