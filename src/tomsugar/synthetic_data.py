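"""Seeded generator of fruit observation tables with the study's structure.

The generator emulates a 4-water x 2-potassium factorial on tomato fruit
sampled at eight ages (34–73 days after anthesis, 3 replicates), with

* logistic fresh- and dry-weight growth, asymptotes scaled per treatment
  so the well-watered control outgrows the deficit treatments and
  potassium raises dry weight;
* smooth carbon-allocation trajectories: the soluble fraction rises
  (9% → 45% of total carbon over the sampled window), the structural
  fraction falls (75% → 53%), and starch is the residual, declining from
  16% early to 2% at maturation;
* deficit irrigation and potassium both shifting allocation toward
  soluble sugar at the expense of structural carbon (starch untouched),
  matching the observed treatment orderings;
* multiplicative lognormal measurement noise (default CV 5%) applied
  independently to FW, DW, SSC and STC — positive-valued assays with
  roughly constant coefficient of variation;
* a daily sinusoidal air temperature between the site bounds
  (14.8–29.1 degC), hourly grid.

One global seed drives an independent substream per treatment, so adding
treatments never reshuffles existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_model import (
    EnvironmentSeries,
    GrowthCurve,
    HOURS_PER_DAY,
    ModelConstants,
    daa_to_hours,
    supply_rate,
)
from .units import SUGAR_CARBON_FRACTION, STARCH_CARBON_FRACTION

WATER_LEVELS = ("T1", "T2", "T3", "CK")
POTASSIUM_LEVELS = ("K0", "K1")
TREATMENT_ORDER = tuple((w, k) for w in WATER_LEVELS for k in POTASSIUM_LEVELS)

#: truss from which fruits of a given sampling age were picked
TRUSS_OF_DAA = {34: 1, 37: 2, 48: 2, 57: 2, 58: 3, 65: 3, 66: 4, 73: 4}


def stage_of_daa(daa) -> np.ndarray:
    """Growth stage of a sampled fruit: II for 34–57 DAA, III for 58–73."""
    return np.where(np.asarray(daa, dtype=float) < 57.5, "II", "III")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic factorial experiment."""

    seed: int = 0
    n_replicates: int = 3
    sampling_daa: tuple = (34, 37, 48, 57, 58, 65, 66, 73)
    noise_cv: float = 0.05

    # logistic growth (control): value = max / (1 + exp(-(age-mid)/tau))
    fw_max: float = 140.0
    fw_mid: float = 46.0
    fw_tau: float = 9.0
    dw_max: float = 7.0
    dw_mid: float = 48.0
    dw_tau: float = 10.0

    # allocation profile: logistics anchored at the first/last sampled age
    anchor_early: float = 34.0
    anchor_late: float = 73.0
    sol_start: float = 9.0
    sol_end: float = 45.0
    sol_mid: float = 52.0
    sol_tau: float = 9.0
    str_start: float = 75.0
    str_end: float = 53.0
    str_mid: float = 48.0
    str_tau: float = 8.0

    # treatment effect multipliers (control CK / K0 = 1)
    fw_mult: dict = field(
        default_factory=lambda: {"T1": 0.783, "T2": 0.727, "T3": 0.765, "CK": 1.0}
    )
    dw_mult: dict = field(
        default_factory=lambda: {"T1": 0.815, "T2": 0.958, "T3": 0.889, "CK": 1.0}
    )
    sol_mult: dict = field(
        default_factory=lambda: {"T1": 1.037, "T2": 1.067, "T3": 1.055, "CK": 1.0}
    )
    k_fw_mult: float = 1.078
    k_dw_mult: float = 1.168
    k_sol_mult: float = 1.074

    temp_min: float = 14.8
    temp_max: float = 29.1

    sugar_cf: float = SUGAR_CARBON_FRACTION
    starch_cf: float = STARCH_CARBON_FRACTION

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.temp_min > self.temp_max:
            raise ValueError("temperature bounds out of order")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _logistic(age, mid, tau):
    return 1.0 / (1.0 + np.exp(-(np.asarray(age, dtype=float) - mid) / tau))


def _anchored_logistic(age, start, end, mid, tau, a0, a1):
    """Logistic rescaled to pass exactly through (a0, start) and (a1, end)."""
    L = _logistic(age, mid, tau)
    L0, L1 = _logistic(a0, mid, tau), _logistic(a1, mid, tau)
    return start + (end - start) * (L - L0) / (L1 - L0)


@dataclass
class TrueTrajectory:
    """Noiseless per-treatment curves and the rates they imply."""

    water: str
    potassium: str
    daa: np.ndarray
    DW: np.ndarray
    FW: np.ndarray
    frac_sol: np.ndarray
    frac_sta: np.ndarray
    frac_str: np.ndarray
    C_sol: np.ndarray
    C_sta: np.ndarray
    C_str: np.ndarray
    k3: np.ndarray
    k5m: np.ndarray
    supply_per_day: np.ndarray

    @property
    def label(self) -> str:
        return self.water + ("K" if self.potassium == "K1" else "")

    def at(self, daa):
        """Interpolate every curve at the requested ages."""
        daa = np.asarray(daa, dtype=float)
        cols = {}
        for name in (
            "DW", "FW", "frac_sol", "frac_sta", "frac_str",
            "C_sol", "C_sta", "C_str", "k3", "k5m", "supply_per_day",
        ):
            cols[name] = np.interp(daa, self.daa, getattr(self, name))
        cols["DAA"] = daa
        return pd.DataFrame(cols)

    def to_frame(self) -> pd.DataFrame:
        df = self.at(self.daa)
        df.insert(0, "water", self.water)
        df.insert(1, "potassium", self.potassium)
        df.insert(2, "treatment", self.label)
        return df


def generate_growth(
    water: str,
    potassium: str,
    config: GeneratorConfig = GeneratorConfig(),
    t_end_daa: float = 73.0,
) -> GrowthCurve:
    """Logistic DW/FW curves for one treatment, hourly grid from anthesis."""
    fw_scale = config.fw_mult[water] * (config.k_fw_mult if potassium == "K1" else 1.0)
    dw_scale = config.dw_mult[water] * (config.k_dw_mult if potassium == "K1" else 1.0)
    t_h = np.arange(0.0, t_end_daa * HOURS_PER_DAY + 0.5, 1.0)
    age = t_h / HOURS_PER_DAY
    Ld = _logistic(age, config.dw_mid, config.dw_tau)
    Lf = _logistic(age, config.fw_mid, config.fw_tau)
    DW = config.dw_max * dw_scale * Ld
    FW = config.fw_max * fw_scale * Lf
    dDW_per_day = DW * (1.0 - Ld) / config.dw_tau
    return GrowthCurve(t_h=t_h, DW=DW, FW=FW, dDWdt=dDW_per_day / HOURS_PER_DAY)


def generate_allocation(
    water: str,
    potassium: str,
    config: GeneratorConfig = GeneratorConfig(),
    const: ModelConstants = ModelConstants(),
    daa_grid: np.ndarray | None = None,
) -> TrueTrajectory:
    """Noiseless allocation trajectory and the rates it implies.

    The soluble and structural fractions are anchored logistics; starch
    is the residual so fractions sum to 100 at every age.  Treatment
    effects multiply the soluble curve and are absorbed by the
    structural curve, leaving starch common to all treatments.  Implied
    k3(t) and k5m(t) follow from the balance equations applied to the
    noiseless pools (dense finite differences).
    """
    if daa_grid is None:
        daa_grid = np.arange(config.anchor_early - 6.0, config.anchor_late + 1e-9, 0.25)
    daa_grid = np.asarray(daa_grid, dtype=float)

    sol_scale = config.sol_mult[water] * (config.k_sol_mult if potassium == "K1" else 1.0)
    sol = sol_scale * _anchored_logistic(
        daa_grid, config.sol_start, config.sol_end,
        config.sol_mid, config.sol_tau, config.anchor_early, config.anchor_late,
    )
    str_base = _anchored_logistic(
        daa_grid, config.str_start, config.str_end,
        config.str_mid, config.str_tau, config.anchor_early, config.anchor_late,
    )
    sol_base = sol / sol_scale
    stru = str_base - (sol - sol_base)  # absorb the treatment shift; starch unchanged
    sta = 100.0 - sol - stru
    if np.any(sta < 0) or np.any(stru < 0) or np.any(sol < 0):
        raise ValueError("allocation profile went negative; check generator parameters")

    growth = generate_growth(water, potassium, config)
    DW = growth.dw_at(daa_to_hours(daa_grid))
    FW = growth.fw_at(daa_to_hours(daa_grid))
    total_c = const.c_DW * DW
    C_sol = sol / 100.0 * total_c
    C_sta = sta / 100.0 * total_c
    C_str = stru / 100.0 * total_c

    dC_str = np.gradient(C_str, daa_grid)
    dC_sta = np.gradient(C_sta, daa_grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        k3 = np.where(C_sol > 0, dC_str / np.where(C_sol > 0, C_sol, 1.0), np.nan)
        k5m = np.where(
            C_sol > 0,
            (const.k5 * C_sta + dC_sta) / np.where(C_sol > 0, C_sol, 1.0),
            np.nan,
        )

    env = generate_temperature(config)
    ddw_day = growth.ddwdt_at(daa_to_hours(daa_grid))
    supply_day = supply_rate(ddw_day, DW, env.at(daa_to_hours(daa_grid)), const) * HOURS_PER_DAY

    return TrueTrajectory(
        water=water,
        potassium=potassium,
        daa=daa_grid,
        DW=DW,
        FW=FW,
        frac_sol=sol,
        frac_sta=sta,
        frac_str=stru,
        C_sol=C_sol,
        C_sta=C_sta,
        C_str=C_str,
        k3=k3,
        k5m=k5m,
        supply_per_day=supply_day,
    )


def _noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-preserving multiplicative lognormal factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def sample_observations(
    truth: TrueTrajectory,
    config: GeneratorConfig = GeneratorConfig(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Noisy observation table for one treatment.

    Curves are evaluated at the sampling ages, pools back-converted to
    assay concentrations (SSC/STC), and independent lognormal noise
    applied per replicate and variable.
    """
    if rng is None:
        rng = rng_for_treatment(config.seed, truth.water, truth.potassium)
    rows = []
    curves = truth.at(np.asarray(config.sampling_daa, dtype=float))
    for _, row in curves.iterrows():
        ssc_true = row["C_sol"] / config.sugar_cf / row["FW"] * 100.0
        stc_true = row["C_sta"] / config.starch_cf / row["FW"] * 100.0
        f = _noise_factors(rng, config.noise_cv, (config.n_replicates, 4))
        for rep in range(config.n_replicates):
            rows.append(
                {
                    "treatment": truth.label,
                    "water": truth.water,
                    "potassium": truth.potassium,
                    "truss": TRUSS_OF_DAA.get(int(row["DAA"]), 0),
                    "replicate": rep + 1,
                    "DAA": row["DAA"],
                    "FW": row["FW"] * f[rep, 0],
                    "DW": row["DW"] * f[rep, 1],
                    "SSC": ssc_true * f[rep, 2],
                    "STC": stc_true * f[rep, 3],
                }
            )
    df = pd.DataFrame(rows)
    df["stage"] = stage_of_daa(df["DAA"])
    return df


def generate_temperature(
    config: GeneratorConfig = GeneratorConfig(),
    t_end_daa: float = 73.0,
) -> EnvironmentSeries:
    """Daily sinusoid between the configured bounds, hourly grid.

    Minimum at 05:00, maximum at 17:00 local time each day.
    """
    t_h = np.arange(0.0, t_end_daa * HOURS_PER_DAY + 0.5, 1.0)
    mean = (config.temp_min + config.temp_max) / 2.0
    amp = (config.temp_max - config.temp_min) / 2.0
    T = mean - amp * np.cos(2.0 * np.pi * (t_h % 24.0 - 5.0) / 24.0)
    return EnvironmentSeries(t_h=t_h, T=T)


def rng_for_treatment(seed: int, water: str, potassium: str) -> np.random.Generator:
    """Independent, order-stable random stream for one treatment."""
    idx = TREATMENT_ORDER.index((water, potassium))
    return np.random.default_rng(np.random.SeedSequence((int(seed), idx)))


def generate_dataset(
    config: GeneratorConfig = GeneratorConfig(),
    const: ModelConstants = ModelConstants(),
) -> tuple[pd.DataFrame, dict]:
    """Observation table for all 8 treatments plus the noiseless truths."""
    tables = []
    truths = {}
    for water, potassium in TREATMENT_ORDER:
        truth = generate_allocation(water, potassium, config, const)
        truths[(water, potassium)] = truth
        tables.append(sample_observations(truth, config))
    return pd.concat(tables, ignore_index=True), truths


def truth_table(truths: dict) -> pd.DataFrame:
    """Stack noiseless trajectories (with implied rates) into one table."""
    return pd.concat([t.to_frame() for t in truths.values()], ignore_index=True)
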