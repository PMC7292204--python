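"""Recover time-varying conversion rates from observed pool trajectories.

Given carbon pools measured at a handful of ages, the conversion
coefficients follow algebraically from the balance equations once the
trajectories and their time derivatives are known:

    k3(t)  = (dC_str/dt) / C_sol
    k5m(t) = k5 * C_sta / C_sol + (dC_sta/dt) / C_sol

so the whole inverse problem reduces to estimating smooth pool curves and
their derivatives.  Pools are smoothed by local quadratic regression with
tricube weights (degree 2 gives first derivatives that are unbiased for
the curvature typical of sigmoidal growth); the derivative at each grid
point is the analytic first derivative of the local polynomial.

Rates are per **day** throughout this module (DAA clock); the forward
integrator converts internally.

Edge policy: local-regression derivatives are unreliable at the window
boundaries, so rate series are reported on the interior 80% of the
observed DAA span by default.  Smoothed *values* remain available on the
full span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    CarbonPools,
    ConfigurationError,
    EnvironmentSeries,
    GrowthCurve,
    HOURS_PER_DAY,
    ModelConstants,
    RateSchedule,
    daa_to_hours,
    respiration_rate,
    simulate_forward,
    supply_rate,
)
from .units import pools_table

logger = logging.getLogger("tomsugar")

#: C_sol floor (g) below which the rate-formula divisions are withheld
CSOL_FLOOR = 1e-6
#: default bandwidth as a fraction of the observed DAA span
DEFAULT_BANDWIDTH = 0.6
#: default interior fraction of the DAA span on which rates are reported
DEFAULT_EDGE_KEEP = 0.8


class EstimationError(RuntimeError):
    """Smoothing or rate estimation could not be carried out."""


# ---------------------------------------------------------------------------
# Local polynomial smoothing
# ---------------------------------------------------------------------------

def local_polynomial_smooth(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    bandwidth: float,
    degree: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Local weighted polynomial fit; returns (value, first derivative).

    ``bandwidth`` is a fraction of the span of ``x``: the tricube kernel
    w(u) = (1-|u|^3)^3 uses half-width h = bandwidth * (max(x)-min(x)).
    At grid points whose window holds fewer than ``degree+1`` points the
    window is widened to the nearest ``degree+1`` observations so that
    boundary estimates remain defined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if len(np.unique(x)) < 4:
        raise EstimationError("local regression needs at least 4 distinct time points")
    span = x.max() - x.min()
    if span <= 0:
        raise EstimationError("degenerate time span")
    if bandwidth <= 0:
        raise EstimationError("bandwidth must be positive")
    h = bandwidth * span

    values = np.empty_like(grid)
    derivs = np.empty_like(grid)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h_i = h
        if np.sum(d < h_i) < degree + 1:
            # widen to the nearest degree+1 points (plus a hair) so the
            # weighted design matrix has full rank
            h_i = np.sort(d)[degree] * 1.0001
            if h_i <= 0:
                raise EstimationError(
                    f"window at grid point {x0:g} is empty; increase the bandwidth"
                )
        u = d / h_i
        w = np.where(u < 1, (1 - u**3) ** 3, 0.0)
        mask = w > 0
        if mask.sum() < degree + 1:
            raise EstimationError(
                f"window at grid point {x0:g} holds too few points; increase the bandwidth"
            )
        # weighted LS on centred abscissa: value = c0, derivative = c1
        xc = x[mask] - x0
        sw = np.sqrt(w[mask])
        A = np.vander(xc, degree + 1, increasing=True) * sw[:, None]
        b = y[mask] * sw
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        values[i] = coef[0]
        derivs[i] = coef[1] if degree >= 1 else 0.0
    return values, derivs


@dataclass
class SmoothedTrajectory:
    """Smoothed pools (g) and their derivatives (g/day) on a DAA grid."""

    daa: np.ndarray
    C_sol: np.ndarray
    C_sta: np.ndarray
    C_str: np.ndarray
    dC_sol: np.ndarray
    dC_sta: np.ndarray
    dC_str: np.ndarray
    bandwidth: float

    def fractions(self) -> pd.DataFrame:
        """Percent pool shares of total carbon along the grid."""
        total = self.C_sol + self.C_sta + self.C_str
        return pd.DataFrame(
            {
                "DAA": self.daa,
                "frac_sol": self.C_sol / total * 100.0,
                "frac_sta": self.C_sta / total * 100.0,
                "frac_str": self.C_str / total * 100.0,
                "total_carbon_g": total,
            }
        )


def smooth_pools(
    records: pd.DataFrame,
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid: np.ndarray | None = None,
    grid_step: float = 1.0,
) -> SmoothedTrajectory:
    """Fit one local-quadratic curve per pool to replicate records.

    ``records`` needs columns DAA, C_sol, C_sta, C_str; replicates are
    pooled into a single regression (one curve per treatment).  Smoothed
    pool values are floored at 0.
    """
    for col in ("DAA", "C_sol", "C_sta", "C_str"):
        if col not in records.columns:
            raise ConfigurationError(f"pool records are missing column {col}")
    daa = records["DAA"].to_numpy(dtype=float)
    if grid is None:
        grid = np.arange(daa.min(), daa.max() + grid_step / 2, grid_step)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ConfigurationError("evaluation grid must be strictly increasing")

    out = {}
    for col in ("C_sol", "C_sta", "C_str"):
        val, der = local_polynomial_smooth(daa, records[col].to_numpy(dtype=float), grid, bandwidth)
        floored = np.maximum(val, 0.0)
        if np.any(val < 0):
            logger.info("smooth_pools: floored negative smoothed %s at %d point(s)", col, int((val < 0).sum()))
        out[col] = (floored, der)
    return SmoothedTrajectory(
        daa=grid,
        C_sol=out["C_sol"][0],
        C_sta=out["C_sta"][0],
        C_str=out["C_str"][0],
        dC_sol=out["C_sol"][1],
        dC_sta=out["C_sta"][1],
        dC_str=out["C_str"][1],
        bandwidth=bandwidth,
    )


# ---------------------------------------------------------------------------
# Rate estimation
# ---------------------------------------------------------------------------

@dataclass
class RateSeries:
    """Estimated conversion/respiration rates on a DAA grid (per day).

    ``raw_*`` keep pre-floor estimates for diagnostics; ``flag`` marks
    points where C_sol fell below the floor or an estimate went negative.
    """

    daa: np.ndarray
    k3: np.ndarray
    k5m: np.ndarray
    k6: np.ndarray = None
    dCsup_dt: np.ndarray = None
    raw_k3: np.ndarray = None
    raw_k5m: np.ndarray = None
    flag: np.ndarray = None
    k5: float = ModelConstants.k5

    def to_frame(self) -> pd.DataFrame:
        n = len(self.daa)
        def col(a):
            return a if a is not None else np.full(n, np.nan)
        return pd.DataFrame(
            {
                "DAA": self.daa,
                "k3": col(self.k3),
                "k5m": col(self.k5m),
                "k6": col(self.k6),
                "dCsup_dt": col(self.dCsup_dt),
                "raw_k3": col(self.raw_k3),
                "raw_k5m": col(self.raw_k5m),
                "flag": self.flag if self.flag is not None else np.zeros(n, dtype=int),
            }
        )


def _guarded_ratio(numer: np.ndarray, c_sol: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    low = c_sol <= CSOL_FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(low, np.nan, numer / np.where(low, 1.0, c_sol))
    return raw, low


def estimate_k3(smoothed: SmoothedTrajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """k3(t) = (dC_str/dt)/C_sol; returns (floored, raw, flags)."""
    raw, low = _guarded_ratio(smoothed.dC_str, smoothed.C_sol)
    floored = np.where(np.isnan(raw), np.nan, np.maximum(raw, 0.0))
    flags = low | (raw < 0)
    return floored, raw, flags


def estimate_k5m(smoothed: SmoothedTrajectory, k5: float = ModelConstants.k5):
    """k5m(t) = k5*C_sta/C_sol + (dC_sta/dt)/C_sol; returns (floored, raw, flags)."""
    raw, low = _guarded_ratio(k5 * smoothed.C_sta + smoothed.dC_sta, smoothed.C_sol)
    floored = np.where(np.isnan(raw), np.nan, np.maximum(raw, 0.0))
    flags = low | (raw < 0)
    return floored, raw, flags


def estimate_supply_flux(
    growth: GrowthCurve,
    env: EnvironmentSeries,
    const: ModelConstants = ModelConstants(),
    t_h: np.ndarray | None = None,
) -> np.ndarray:
    """Instantaneous phloem supply flux dC_sup/dt (g C/h) on ``t_h``.

    Mass conservation: supply = c_DW*dDW/dt + respiration.
    """
    if t_h is None:
        t_h = growth.t_h
    t_h = np.asarray(t_h, dtype=float)
    return supply_rate(growth.ddwdt_at(t_h), growth.dw_at(t_h), env.at(t_h), const)


def fit_growth_from_observations(
    observations: pd.DataFrame,
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_step_daa: float = 0.25,
) -> GrowthCurve:
    """Local-regression fit of DW(t), FW(t) from an observation table.

    Returns a :class:`GrowthCurve` on an hourly clock with the derivative
    taken from the local polynomial (converted to g/h).
    """
    for col in ("DAA", "DW", "FW"):
        if col not in observations.columns:
            raise ConfigurationError(f"observations are missing column {col}")
    daa = observations["DAA"].to_numpy(dtype=float)
    grid = np.arange(daa.min(), daa.max() + grid_step_daa / 2, grid_step_daa)
    dw, ddw = local_polynomial_smooth(daa, observations["DW"].to_numpy(dtype=float), grid, bandwidth)
    fw, _ = local_polynomial_smooth(daa, observations["FW"].to_numpy(dtype=float), grid, bandwidth)
    return GrowthCurve(
        t_h=daa_to_hours(grid),
        DW=np.maximum(dw, 0.0),
        FW=np.maximum(fw, 0.0),
        dDWdt=np.maximum(ddw, 0.0) / HOURS_PER_DAY,
    )


def interior_window(daa_min: float, daa_max: float, keep: float = DEFAULT_EDGE_KEEP):
    """Interior ``keep`` fraction of a DAA span (rate-reporting window)."""
    pad = (1.0 - keep) / 2.0 * (daa_max - daa_min)
    return daa_min + pad, daa_max - pad


def invert_rates(
    observations: pd.DataFrame,
    env: EnvironmentSeries,
    const: ModelConstants = ModelConstants(),
    k5: float | None = None,
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_step: float = 1.0,
    edge_keep: float = DEFAULT_EDGE_KEEP,
    sugar_cf: float | None = None,
    starch_cf: float | None = None,
) -> tuple[RateSeries, SmoothedTrajectory]:
    """Full inversion for one treatment's observation table.

    Converts assays to pools, smooths, and evaluates k3(t), k5m(t),
    k6(t) and the supply flux on the interior window.  Fluxes and k6 are
    reported per day (dCsup_dt in g/day).
    """
    kw = {}
    if sugar_cf is not None:
        kw["sugar_cf"] = sugar_cf
    if starch_cf is not None:
        kw["starch_cf"] = starch_cf
    pools = pools_table(observations, const=const, **kw)
    if k5 is None:
        k5 = const.k5
    smoothed = smooth_pools(pools, bandwidth=bandwidth, grid_step=grid_step)

    lo, hi = interior_window(smoothed.daa.min(), smoothed.daa.max(), edge_keep)
    keep = (smoothed.daa >= lo - 1e-9) & (smoothed.daa <= hi + 1e-9)
    sub = SmoothedTrajectory(
        daa=smoothed.daa[keep],
        C_sol=smoothed.C_sol[keep],
        C_sta=smoothed.C_sta[keep],
        C_str=smoothed.C_str[keep],
        dC_sol=smoothed.dC_sol[keep],
        dC_sta=smoothed.dC_sta[keep],
        dC_str=smoothed.dC_str[keep],
        bandwidth=bandwidth,
    )

    k3, raw_k3, f3 = estimate_k3(sub)
    k5m, raw_k5m, f5 = estimate_k5m(sub, k5)

    growth = fit_growth_from_observations(observations, bandwidth=bandwidth)
    t_h = daa_to_hours(sub.daa)
    sup_h = estimate_supply_flux(growth, env, const, t_h)
    rep_h = respiration_rate(growth.dw_at(t_h), growth.ddwdt_at(t_h), env.at(t_h), const)
    with np.errstate(divide="ignore", invalid="ignore"):
        k6 = np.where(sub.C_sol > CSOL_FLOOR, rep_h * HOURS_PER_DAY / np.maximum(sub.C_sol, CSOL_FLOOR), np.nan)

    series = RateSeries(
        daa=sub.daa,
        k3=k3,
        k5m=k5m,
        k6=k6,
        dCsup_dt=sup_h * HOURS_PER_DAY,
        raw_k3=raw_k3,
        raw_k5m=raw_k5m,
        flag=(f3 | f5).astype(int),
        k5=k5,
    )
    return series, smoothed


# ---------------------------------------------------------------------------
# k5 calibration
# ---------------------------------------------------------------------------

def _simulation_sse(
    k5: float,
    smoothed: SmoothedTrajectory,
    growth: GrowthCurve,
    env: EnvironmentSeries,
    const: ModelConstants,
    obs_pools: pd.DataFrame,
    step: float,
) -> float:
    """SSE between a forward run (rates re-derived at this k5) and observations."""
    k3, _, _ = estimate_k3(smoothed)
    k5m, _, _ = estimate_k5m(smoothed, k5)
    ok = ~(np.isnan(k3) | np.isnan(k5m))
    if ok.sum() < 2:
        return np.inf
    rates = RateSchedule(smoothed.daa[ok], k3[ok], k5m[ok], k5_per_day=k5)
    init = CarbonPools(
        float(smoothed.C_sol[ok][0]),
        float(smoothed.C_sta[ok][0]),
        float(smoothed.C_str[ok][0]),
    )
    sim = simulate_forward(init, growth, env, rates, const, step=step)
    sse = 0.0
    for col, sim_vals in (("C_sol", sim.C_sol), ("C_sta", sim.C_sta), ("C_str", sim.C_str)):
        obs_t = daa_to_hours(obs_pools["DAA"].to_numpy(dtype=float))
        inside = (obs_t >= sim.t_h[0]) & (obs_t <= sim.t_h[-1])
        pred = np.interp(obs_t[inside], sim.t_h, sim_vals)
        sse += float(np.sum((obs_pools[col].to_numpy(dtype=float)[inside] - pred) ** 2))
    return sse


def calibrate_k5(
    observations: pd.DataFrame,
    env: EnvironmentSeries,
    const: ModelConstants = ModelConstants(),
    interval: tuple[float, float] = (0.02, 1.0),
    bandwidth: float = DEFAULT_BANDWIDTH,
    n_scan: int = 25,
    knee_tol: float = 0.02,
    step: float = 2.0,
) -> tuple[float, bool]:
    """Least-squares calibration of the constant starch-breakdown rate k5.

    For each candidate k5 the time-varying rates are re-derived from the
    smoothed pools, the model is run forward, and the summed squared
    deviation from the observed pools is evaluated.

    Identifiability caveat: substituting the derived k5m(t) back into the
    starch balance makes the fit exact for *any* k5, so the data bound k5
    only from below — candidates well under the generating value push
    derived k5m(t) negative near maturation, the non-negativity floor
    engages, and starch decays too slowly, degrading the fit; above that
    point the objective is an uninformative plateau.  The calibrated
    value is therefore the smallest candidate whose SSE is within
    ``knee_tol`` (relative) of the plateau minimum: the most parsimonious
    starch-breakdown rate consistent with the trajectories.

    Returns ``(k5, flat_flag)``; ``flat_flag`` is True when the objective
    carries no information (starch ≈ 0 throughout), in which case the
    interval midpoint is returned with a warning.
    """
    pools = pools_table(observations, const=const)
    smoothed = smooth_pools(pools, bandwidth=bandwidth)
    growth = fit_growth_from_observations(observations, bandwidth=bandwidth)

    if float(np.max(smoothed.C_sta)) < 1e-3 * float(np.max(smoothed.C_sol + smoothed.C_str + smoothed.C_sta)):
        logger.warning("calibrate_k5: starch ≈ 0 throughout; objective is flat, returning interval midpoint")
        return (interval[0] + interval[1]) / 2.0, True

    candidates = np.linspace(interval[0], interval[1], n_scan)
    sse = np.array(
        [_simulation_sse(k, smoothed, growth, env, const, pools, step) for k in candidates]
    )
    finite = np.isfinite(sse)
    if not finite.any() or (np.nanmax(sse[finite]) - np.nanmin(sse[finite])) <= 1e-12 * max(np.nanmax(sse[finite]), 1e-30):
        logger.warning("calibrate_k5: flat objective over the search interval; returning midpoint")
        return (interval[0] + interval[1]) / 2.0, True

    sse_min = np.nanmin(sse[finite])
    threshold = sse_min * (1.0 + knee_tol)
    below = candidates[finite & (sse <= threshold)]
    knee = float(below[0])

    # refine the knee by bisection on the threshold crossing
    idx = int(np.where(candidates == below[0])[0][0])
    if idx > 0 and np.isfinite(sse[idx - 1]):
        lo, hi = candidates[idx - 1], candidates[idx]
        for _ in range(20):
            mid = (lo + hi) / 2.0
            if _simulation_sse(mid, smoothed, growth, env, const, pools, step) <= threshold:
                hi = mid
            else:
                lo = mid
        knee = float(hi)
    return knee, False
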