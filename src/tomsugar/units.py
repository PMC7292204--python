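"""Convert field measurements into carbon amounts and fractions.

A sampled fruit carries fresh weight FW (g), dry weight DW (g), soluble
sugar concentration SSC (g sugar / 100 g FW) and starch concentration STC
(g starch / 100 g FW).  The model works in grams of *carbon*, so assay
masses are scaled by the carbon fraction of the compound class:

* soluble sugar: tomato soluble sugars are predominantly glucose +
  fructose, so the hexose stoichiometry C6H12O6 gives 72/180 = 0.40
  g C / g sugar;
* starch: (C6H10O5)n gives 72/162 ≈ 0.444 g C / g starch.

Structural carbon is the remainder of total fruit carbon (c_DW * DW)
after the soluble and starch pools are subtracted.  Records whose implied
structural carbon is negative signal assay error and are excluded (with a
log entry), not clipped — clipping would bias downstream rate estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import CarbonPools, ConfigurationError, DomainError, ModelConstants

logger = logging.getLogger("tomsugar")

#: default carbon mass fraction of soluble sugar (hexose, 72/180)
SUGAR_CARBON_FRACTION = 0.40
#: default carbon mass fraction of starch ((C6H10O5)n, 72/162)
STARCH_CARBON_FRACTION = 72.0 / 162.0

OBSERVATION_COLUMNS = [
    "treatment",
    "water",
    "potassium",
    "replicate",
    "DAA",
    "FW",
    "DW",
    "SSC",
    "STC",
]


@dataclass(frozen=True)
class FruitObservation:
    """One sampled fruit."""

    treatment: str
    water: str
    potassium: str
    replicate: int
    DAA: float
    FW: float
    DW: float
    SSC: float
    STC: float
    truss: int = 0

    def __post_init__(self):
        if not (0 < self.DW < self.FW):
            raise DomainError("expected 0 < DW < FW for a fresh fruit")
        if self.SSC < 0 or self.STC < 0:
            raise DomainError("concentrations must be non-negative")


@dataclass(frozen=True)
class CarbonFractionRecord:
    """Pool shares of total fruit carbon at one age, in percent."""

    DAA: float
    frac_sol: float
    frac_sta: float
    frac_str: float
    total_carbon: float

    def __post_init__(self):
        s = self.frac_sol + self.frac_sta + self.frac_str
        if self.total_carbon > 0 and abs(s - 100.0) > 0.01:
            raise DomainError(f"fractions sum to {s:.4f}, expected 100")


class InconsistentRecordError(DomainError):
    """Assayed sugar + starch carbon exceeds total carbon from DW."""


def pools_from_observation(
    obs: FruitObservation,
    sugar_cf: float = SUGAR_CARBON_FRACTION,
    starch_cf: float = STARCH_CARBON_FRACTION,
    const: ModelConstants = ModelConstants(),
) -> CarbonPools:
    """Carbon pools (g) implied by one fruit's assays.

    C_sol = SSC/100 * FW * sugar_cf;  C_sta = STC/100 * FW * starch_cf;
    C_str = c_DW * DW - C_sol - C_sta.
    """
    if not (0 < sugar_cf < 1) or not (0 < starch_cf < 1):
        raise DomainError("carbon conversion factors must lie in (0, 1)")
    c_sol = obs.SSC / 100.0 * obs.FW * sugar_cf
    c_sta = obs.STC / 100.0 * obs.FW * starch_cf
    c_str = const.c_DW * obs.DW - c_sol - c_sta
    if c_str < 0:
        raise InconsistentRecordError(
            f"record (treatment={obs.treatment}, DAA={obs.DAA}, rep={obs.replicate}) "
            f"implies negative structural carbon ({c_str:.4g} g)"
        )
    return CarbonPools(c_sol, c_sta, c_str)


def fractions_from_pools(pools: CarbonPools, DAA: float = float("nan")) -> CarbonFractionRecord:
    """Percent shares of total carbon for one set of pools."""
    total = pools.total
    if total <= 0:
        raise DomainError("total carbon must be positive to form fractions")
    return CarbonFractionRecord(
        DAA=DAA,
        frac_sol=pools.C_sol / total * 100.0,
        frac_sta=pools.C_sta / total * 100.0,
        frac_str=pools.C_str / total * 100.0,
        total_carbon=total,
    )


def observation_to_concentrations(
    pools: CarbonPools,
    FW: float,
    sugar_cf: float = SUGAR_CARBON_FRACTION,
    starch_cf: float = STARCH_CARBON_FRACTION,
) -> tuple[float, float]:
    """Back-convert pools to (SSC, STC) in g / 100 g FW.

    Exact inverse of :func:`pools_from_observation` for the same factors.
    """
    if FW <= 0:
        raise DomainError("fresh weight must be positive")
    ssc = pools.C_sol / sugar_cf / FW * 100.0
    stc = pools.C_sta / starch_cf / FW * 100.0
    return ssc, stc


def pools_table(
    observations: pd.DataFrame,
    sugar_cf: float = SUGAR_CARBON_FRACTION,
    starch_cf: float = STARCH_CARBON_FRACTION,
    const: ModelConstants = ModelConstants(),
) -> pd.DataFrame:
    """Vectorised pool conversion for an observation table.

    Returns the input with ``C_sol``, ``C_sta``, ``C_str`` columns
    appended; rows with negative implied structural carbon are dropped
    and logged.
    """
    require_columns(observations, ["DAA", "FW", "DW", "SSC", "STC"])
    df = observations.copy()
    df["C_sol"] = df["SSC"] / 100.0 * df["FW"] * sugar_cf
    df["C_sta"] = df["STC"] / 100.0 * df["FW"] * starch_cf
    df["C_str"] = const.c_DW * df["DW"] - df["C_sol"] - df["C_sta"]
    bad = df["C_str"] < 0
    if bad.any():
        logger.warning(
            "pools_table: excluding %d record(s) with negative implied structural carbon",
            int(bad.sum()),
        )
        df = df.loc[~bad]
    return df


# ---------------------------------------------------------------------------
# CSV contracts
# ---------------------------------------------------------------------------

def require_columns(df: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ConfigurationError(f"input table is missing column(s): {', '.join(missing)}")


def read_observations(path) -> pd.DataFrame:
    """Read an observation CSV, validating the header contract."""
    df = pd.read_csv(path)
    if df.empty:
        raise ConfigurationError(f"observation file {path} is empty")
    require_columns(df, OBSERVATION_COLUMNS)
    return df


def write_fractions(records, path) -> None:
    """Write CarbonFractionRecord rows as CSV."""
    pd.DataFrame(
        [
            {
                "DAA": r.DAA,
                "frac_sol": r.frac_sol,
                "frac_sta": r.frac_sta,
                "frac_str": r.frac_str,
                "total_carbon_g": r.total_carbon,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
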