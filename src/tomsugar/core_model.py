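"""Forward representation of the simplified SUGAR carbon-balance model.

The fruit is described by three carbon pools — soluble-sugar carbon
``C_sol``, starch carbon ``C_sta`` and structural carbon ``C_str`` (cell
walls, proteins, organic acids; all in g C) — coupled by first-order
conversion fluxes:

    dC_sol/dt = k0 * dC_sup/dt + k5 * C_sta - (k3(t) + k5m(t) + k6(t)) * C_sol
    dC_sta/dt = k5m(t) * C_sol - k5 * C_sta
    dC_str/dt = k3(t) * C_sol

Carbon enters through the phloem (supply flux ``dC_sup/dt``) and leaves as
respired CO2 at rate ``dC_rep/dt = k6(t) * C_sol``, split into a growth
component proportional to the dry-weight growth rate and a maintenance
component proportional to standing dry weight with a Q10 temperature
response.  Mass conservation ties the supply flux to growth:

    c_DW * dDW/dt = dC_sup/dt - dC_rep/dt

Internal clock is **hours** since anthesis (the respiration constants are
per hour).  User-facing rate schedules (k3, k5m, k5) are per **day**; the
day->hour conversion happens in exactly one function,
:func:`per_day_to_per_hour`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("tomsugar")

HOURS_PER_DAY = 24.0


class DomainError(ValueError):
    """An argument is outside the physical domain of an operation."""


class ConfigurationError(ValueError):
    """Input series do not cover the requested computation."""


def per_day_to_per_hour(rate_per_day):
    """Convert a relative rate (or flux) from 1/day to 1/hour.

    This is the single place where the day/hour conversion factor is
    applied; every internal computation works in hours.
    """
    return np.asarray(rate_per_day, dtype=float) / HOURS_PER_DAY


def per_hour_to_per_day(rate_per_hour):
    """Inverse of :func:`per_day_to_per_hour`."""
    return np.asarray(rate_per_hour, dtype=float) * HOURS_PER_DAY


def daa_to_hours(daa):
    """Days after anthesis -> hours after anthesis."""
    return np.asarray(daa, dtype=float) * HOURS_PER_DAY


@dataclass(frozen=True)
class ModelConstants:
    """Fixed parameters of the simplified SUGAR model.

    Attributes
    ----------
    c_DW : float
        Carbon per gram of dry mass (g C / g DW); 0.44 for tomato fruit.
    q_g : float
        Growth respiration coefficient (g C respired / g DW grown).
    q_m : float
        Maintenance respiration coefficient at 20 degC (g C / g DW / h).
    Q10 : float
        Temperature ratio of maintenance respiration per 10 degC step.
    k0 : float
        Fraction of assimilates imported from the phloem; 1 for tomato.
    k5 : float
        Starch -> soluble-sugar relative conversion rate (1/day); held
        constant because amylase / starch-phosphorylase activity varies
        little over tomato fruit development.
    """

    c_DW: float = 0.44
    q_g: float = 0.088
    q_m: float = 0.000168
    Q10: float = 1.4
    k0: float = 1.0
    k5: float = 0.296517337

    def __post_init__(self):
        for name in ("c_DW", "q_g", "q_m", "Q10", "k0", "k5"):
            if getattr(self, name) <= 0:
                raise DomainError(f"ModelConstants.{name} must be strictly positive")

    def with_overrides(self, **kwargs) -> "ModelConstants":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CarbonPools:
    """Carbon amounts (g) in the three fruit pools at one instant."""

    C_sol: float
    C_sta: float
    C_str: float

    def __post_init__(self):
        if min(self.C_sol, self.C_sta, self.C_str) < 0:
            raise DomainError("carbon pools must be non-negative")

    @property
    def total(self) -> float:
        return self.C_sol + self.C_sta + self.C_str

    def as_array(self) -> np.ndarray:
        return np.array([self.C_sol, self.C_sta, self.C_str], dtype=float)


def _interp_checked(t, grid, values, what):
    t = np.asarray(t, dtype=float)
    if np.any(t < grid[0] - 1e-9) or np.any(t > grid[-1] + 1e-9):
        raise ConfigurationError(
            f"{what} grid [{grid[0]:g}, {grid[-1]:g}] h does not cover requested "
            f"time(s) in [{t.min():g}, {t.max():g}] h"
        )
    return np.interp(t, grid, values)


@dataclass
class GrowthCurve:
    """Fruit growth trajectory on an hourly clock.

    ``t_h`` is hours since anthesis; ``DW``/``FW`` in g; ``dDWdt`` in g/h.
    Values between grid points are linearly interpolated.
    """

    t_h: np.ndarray
    DW: np.ndarray
    FW: np.ndarray
    dDWdt: np.ndarray

    def __post_init__(self):
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.DW = np.asarray(self.DW, dtype=float)
        self.FW = np.asarray(self.FW, dtype=float)
        self.dDWdt = np.asarray(self.dDWdt, dtype=float)
        if not (len(self.t_h) == len(self.DW) == len(self.FW) == len(self.dDWdt)):
            raise ConfigurationError("GrowthCurve arrays must share one grid")
        if np.any(np.diff(self.t_h) <= 0):
            raise ConfigurationError("GrowthCurve time grid must be strictly increasing")
        if np.any(self.DW < 0) or np.any(self.FW < 0):
            raise DomainError("DW and FW must be non-negative")

    def dw_at(self, t_h):
        return _interp_checked(t_h, self.t_h, self.DW, "growth")

    def fw_at(self, t_h):
        return _interp_checked(t_h, self.t_h, self.FW, "growth")

    def ddwdt_at(self, t_h):
        return _interp_checked(t_h, self.t_h, self.dDWdt, "growth")


@dataclass
class EnvironmentSeries:
    """Air temperature series (degC) on an hourly clock."""

    t_h: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if len(self.t_h) != len(self.T):
            raise ConfigurationError("EnvironmentSeries grids must match")
        if np.any(np.diff(self.t_h) <= 0):
            raise ConfigurationError("EnvironmentSeries time grid must be strictly increasing")

    def at(self, t_h):
        return _interp_checked(t_h, self.t_h, self.T, "environment")


@dataclass
class RateSchedule:
    """Time-varying conversion rates on a DAA grid, stored per day.

    ``k3`` (soluble -> structural) and ``k5m`` (soluble -> starch) are
    arrays on ``daa``; ``k5`` (starch -> soluble) is the constant from
    :class:`ModelConstants` unless overridden.
    """

    daa: np.ndarray
    k3_per_day: np.ndarray
    k5m_per_day: np.ndarray
    k5_per_day: float = ModelConstants.k5

    def __post_init__(self):
        self.daa = np.asarray(self.daa, dtype=float)
        self.k3_per_day = np.asarray(self.k3_per_day, dtype=float)
        self.k5m_per_day = np.asarray(self.k5m_per_day, dtype=float)
        if not (len(self.daa) == len(self.k3_per_day) == len(self.k5m_per_day)):
            raise ConfigurationError("RateSchedule arrays must share one grid")
        if np.any(np.diff(self.daa) <= 0):
            raise ConfigurationError("RateSchedule DAA grid must be strictly increasing")

    def per_hour_at(self, t_h):
        """(k3, k5m, k5) in 1/h at time ``t_h`` (hours since anthesis)."""
        grid_h = daa_to_hours(self.daa)
        k3 = _interp_checked(t_h, grid_h, self.k3_per_day, "rate schedule")
        k5m = _interp_checked(t_h, grid_h, self.k5m_per_day, "rate schedule")
        return (
            per_day_to_per_hour(k3),
            per_day_to_per_hour(k5m),
            float(per_day_to_per_hour(self.k5_per_day)),
        )


@dataclass
class SimulationResult:
    """Trajectory from :func:`simulate_forward`.

    ``C_rep`` and ``C_sup`` are cumulative respired / supplied carbon (g)
    since the start of the run.
    """

    t_h: np.ndarray
    C_sol: np.ndarray
    C_sta: np.ndarray
    C_str: np.ndarray
    C_rep: np.ndarray
    C_sup: np.ndarray
    clipped_steps: int = 0
    constants: ModelConstants = field(default_factory=ModelConstants)

    @property
    def daa(self):
        return self.t_h / HOURS_PER_DAY

    def pools_at_end(self) -> CarbonPools:
        return CarbonPools(
            float(max(self.C_sol[-1], 0.0)),
            float(max(self.C_sta[-1], 0.0)),
            float(max(self.C_str[-1], 0.0)),
        )

    def conservation_defect(self) -> float:
        """|Δ(total pools) − (C_sup − C_rep)| over the whole run."""
        total = self.C_sol + self.C_sta + self.C_str
        return float(abs((total[-1] - total[0]) - (self.C_sup[-1] - self.C_rep[-1])))

    def to_frame(self):
        import pandas as pd

        frac = fraction_trajectory(self)
        return pd.DataFrame(
            {
                "time_h": self.t_h,
                "DAA": self.daa,
                "C_sol_g": self.C_sol,
                "C_sta_g": self.C_sta,
                "C_str_g": self.C_str,
                "C_rep_g": self.C_rep,
                "C_sup_g": self.C_sup,
                "frac_sol": frac[:, 0],
                "frac_sta": frac[:, 1],
                "frac_str": frac[:, 2],
            }
        )


# ---------------------------------------------------------------------------
# Respiration and supply
# ---------------------------------------------------------------------------

def maintenance_respiration(DW, T, const: ModelConstants = ModelConstants()):
    """Maintenance respiration rate (g C/h): q_m * DW * Q10**((T-20)/10)."""
    DW = np.asarray(DW, dtype=float)
    if np.any(DW < 0):
        raise DomainError("dry weight must be non-negative")
    out = const.q_m * DW * const.Q10 ** ((np.asarray(T, dtype=float) - 20.0) / 10.0)
    return out if out.ndim else float(out)


def respiration_rate(DW, dDWdt, T, const: ModelConstants = ModelConstants()):
    """Total respiration rate (g C/h): growth + maintenance components."""
    dDWdt = np.asarray(dDWdt, dtype=float)
    if np.any(dDWdt < 0):
        raise DomainError("dry-weight growth rate must be non-negative")
    out = const.q_g * dDWdt + maintenance_respiration(DW, T, const)
    return out if np.ndim(out) else float(out)


def carbon_total(DW, const: ModelConstants = ModelConstants()):
    """Total fruit carbon (g): c_DW * DW."""
    DW = np.asarray(DW, dtype=float)
    if np.any(DW < 0):
        raise DomainError("dry weight must be non-negative")
    out = const.c_DW * DW
    return out if out.ndim else float(out)


def supply_rate(dDWdt, DW, T, const: ModelConstants = ModelConstants()):
    """Phloem carbon supply flux dC_sup/dt (g C/h).

    By mass conservation the fruit imports the carbon fixed into dry
    matter plus what it respires: c_DW*dDW/dt + respiration.
    """
    out = const.c_DW * np.asarray(dDWdt, dtype=float) + respiration_rate(DW, dDWdt, T, const)
    return out if np.ndim(out) else float(out)


def k6_of_t(DW, dDWdt, T, C_sol, const: ModelConstants = ModelConstants()):
    """Respiration coefficient k6 = (dC_rep/dt) / C_sol (1/h).

    Directly calculable from growth and temperature, hence never a free
    parameter.  Returns NaN where ``C_sol <= 0`` (undefined).
    """
    rep = respiration_rate(DW, dDWdt, T, const)
    C_sol = np.asarray(C_sol, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(C_sol > 0, rep / np.where(C_sol > 0, C_sol, 1.0), np.nan)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Forward integration
# ---------------------------------------------------------------------------

def simulate_forward(
    init: CarbonPools,
    growth: GrowthCurve,
    env: EnvironmentSeries,
    rates: RateSchedule,
    const: ModelConstants = ModelConstants(),
    step: float = 1.0,
    t_start: float | None = None,
    t_end: float | None = None,
) -> SimulationResult:
    """Integrate the three-pool balance with fixed-step RK4.

    Parameters
    ----------
    step : float
        Integrator step in hours (default 1 h).  Fixed-step RK4 keeps
        runs bit-reproducible; the system is smooth and linear in the
        pools, so adaptive stepping buys nothing.
    t_start, t_end : float, optional
        Simulation window in hours since anthesis; defaults to the span
        of the rate schedule's DAA grid.

    The growth, environment and rate grids must cover the window
    (:class:`ConfigurationError` otherwise).  If the integrator
    transiently undershoots zero — possible because the soluble pool
    funds three outgoing fluxes — pools are clipped at 0 and a warning
    is logged.
    """
    if t_start is None:
        t_start = float(daa_to_hours(rates.daa[0]))
    if t_end is None:
        t_end = float(daa_to_hours(rates.daa[-1]))
    if t_end <= t_start:
        raise ConfigurationError("t_end must exceed t_start")
    if step <= 0:
        raise DomainError("step must be positive")

    # Fail fast on coverage before integrating.
    for t_probe in (t_start, t_end):
        growth.dw_at(t_probe)
        env.at(t_probe)
        rates.per_hour_at(t_probe)

    n_steps = int(np.ceil((t_end - t_start) / step - 1e-12))
    t_grid = t_start + step * np.arange(n_steps + 1)
    t_grid[-1] = t_end

    def deriv(t, y):
        sol, sta, stru, rep, sup = y
        DW = growth.dw_at(t)
        dDW = growth.ddwdt_at(t)
        T = env.at(t)
        k3, k5m, k5 = rates.per_hour_at(t)
        rep_rate = respiration_rate(DW, dDW, T, const)
        sup_rate = const.c_DW * dDW + rep_rate
        dsol = const.k0 * sup_rate + k5 * sta - (k3 + k5m) * sol - rep_rate
        dsta = k5m * sol - k5 * sta
        dstr = k3 * sol
        return np.array([dsol, dsta, dstr, rep_rate, sup_rate], dtype=float)

    y = np.array([init.C_sol, init.C_sta, init.C_str, 0.0, 0.0], dtype=float)
    out = np.empty((n_steps + 1, 5), dtype=float)
    out[0] = y
    clipped = 0
    for i in range(n_steps):
        t = t_grid[i]
        h = t_grid[i + 1] - t
        k1 = deriv(t, y)
        k2 = deriv(t + h / 2, y + h / 2 * k1)
        k3_ = deriv(t + h / 2, y + h / 2 * k2)
        k4 = deriv(t + h, y + h * k3_)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3_ + k4)
        if np.any(y[:3] < 0):
            clipped += 1
            y[:3] = np.maximum(y[:3], 0.0)
        out[i + 1] = y
    if clipped:
        logger.warning("simulate_forward: clipped negative pools at %d step(s)", clipped)

    return SimulationResult(
        t_h=t_grid,
        C_sol=out[:, 0],
        C_sta=out[:, 1],
        C_str=out[:, 2],
        C_rep=out[:, 3],
        C_sup=out[:, 4],
        clipped_steps=clipped,
        constants=const,
    )


def fraction_trajectory(sim: SimulationResult) -> np.ndarray:
    """Per-step pool fractions of total carbon, in percent.

    Returns an (n, 3) array with columns (soluble, starch, structural);
    rows sum to 100 wherever total carbon is positive.
    """
    pools = np.column_stack([sim.C_sol, sim.C_sta, sim.C_str])
    total = pools.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total[:, None] > 0, pools / total[:, None] * 100.0, np.nan)
    return frac
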