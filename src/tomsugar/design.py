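"""Experimental-design arithmetic: irrigation amounts and potassium dosing.

The study design is a 4 (water) x 2 (potassium) factorial on potted
tomato plants.  The control (CK) is well-watered in all three growth
stages; each deficit treatment T1/T2/T3 receives half the control amount
in exactly one stage (I: flowering and fruit-bearing, II: fruit swelling,
III: maturation).  Potassium plots receive two K2O applications of
0.46 g per kg of soil (17 kg pots), i.e. 7.82 g each, 15.64 g total.

Irrigation volume per event refills the pot from the measured soil water
content to an upper limit:  W = (theta_t1 - theta_t2) * V  with theta in
cm3/cm3 and V the pot soil volume in cm3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_model import DomainError

#: volumetric field capacity of the potted sandy loam (cm3/cm3)
FIELD_CAPACITY = 0.25
#: irrigation is triggered when soil water falls to this fraction of field capacity
TRIGGER_FRACTION = 0.70
#: refill target as a fraction of field capacity
REFILL_FRACTION = 0.95
#: pot soil mass (kg) and bulk density (g/cm3) -> default soil volume
SOIL_MASS_KG = 17.0
BULK_DENSITY = 1.3
#: default pot soil volume (cm3): soil mass / bulk density, not the pot
#: geometry (the gravel drainage layer makes geometric volume an overestimate)
DEFAULT_SOIL_VOLUME = SOIL_MASS_KG * 1000.0 / BULK_DENSITY

#: K2O application rate (g per kg soil) and number of applications
K_RATE_G_PER_KG = 0.46
N_K_APPLICATIONS = 2

#: control (well-watered) irrigation per stage, mm
CONTROL_STAGE_AMOUNTS = (60.66, 114.92, 91.64)
STAGE_NAMES = ("I", "II", "III")

WATER_LEVELS = ("T1", "T2", "T3", "CK")
POTASSIUM_LEVELS = ("K0", "K1")
#: which stage (0-based) each deficit treatment halves
DEFICIT_STAGE = {"T1": 0, "T2": 1, "T3": 2}


def irrigation_amount(theta_t1: float, theta_t2: float, V: float) -> float:
    """Irrigation volume (cm3) to refill from theta_t2 up to theta_t1."""
    if theta_t2 < 0 or V <= 0:
        raise DomainError("soil water content and volume must be non-negative/positive")
    if theta_t2 > theta_t1:
        raise DomainError("measured soil water exceeds the upper limit; no irrigation needed")
    return (theta_t1 - theta_t2) * V


@dataclass(frozen=True)
class IrrigationEvent:
    """One irrigation of a pot."""

    stage: str
    theta_t1: float
    theta_t2: float
    V: float = DEFAULT_SOIL_VOLUME
    W: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "W", irrigation_amount(self.theta_t1, self.theta_t2, self.V))


@dataclass(frozen=True)
class TreatmentDesign:
    """Water x potassium treatment with its stage schedule."""

    water: str
    potassium: str
    stage_amounts_mm: tuple[float, float, float]
    k_dose_per_application_g: float
    deficit_stage: str | None

    @property
    def label(self) -> str:
        return self.water + ("K" if self.potassium == "K1" else "")

    @property
    def total_irrigation_mm(self) -> float:
        return round(sum(self.stage_amounts_mm), 10)

    @property
    def total_k_g(self) -> float:
        return self.k_dose_per_application_g * N_K_APPLICATIONS


def build_design(
    control_amounts: tuple[float, float, float] = CONTROL_STAGE_AMOUNTS,
    deficit_map: dict[str, int] = None,
    k_rate_g_per_kg: float = K_RATE_G_PER_KG,
    soil_mass_kg: float = SOIL_MASS_KG,
) -> list[TreatmentDesign]:
    """All 8 water x potassium treatments.

    The deficit stage gets exactly half the control amount; the other two
    stages match the control.  Per-application K2O dose = rate x soil
    mass; total = two applications.
    """
    if deficit_map is None:
        deficit_map = DEFICIT_STAGE
    if len(control_amounts) != 3:
        raise DomainError("expected three stage amounts")
    if k_rate_g_per_kg <= 0:
        raise DomainError("potassium rate must be positive")
    dose = k_rate_g_per_kg * soil_mass_kg

    designs = []
    for water in WATER_LEVELS:
        amounts = list(control_amounts)
        deficit_stage = None
        if water in deficit_map:
            i = deficit_map[water]
            amounts[i] = control_amounts[i] / 2.0
            deficit_stage = STAGE_NAMES[i]
        for potassium in POTASSIUM_LEVELS:
            designs.append(
                TreatmentDesign(
                    water=water,
                    potassium=potassium,
                    stage_amounts_mm=tuple(round(a, 10) for a in amounts),
                    k_dose_per_application_g=dose if potassium == "K1" else 0.0,
                    deficit_stage=deficit_stage,
                )
            )
    return designs


def design_table(designs: list[TreatmentDesign] | None = None) -> pd.DataFrame:
    """Treatment schedule as a table (one row per treatment).

    The total column is the sum of the three stage amounts (printed
    totals in the source schedule additionally include pre-treatment
    irrigation and are not reproduced here).
    """
    if designs is None:
        designs = build_design()
    return pd.DataFrame(
        {
            "treatment": [d.label for d in designs],
            "water": [d.water for d in designs],
            "potassium": [d.potassium for d in designs],
            "stage_I_mm": [d.stage_amounts_mm[0] for d in designs],
            "stage_II_mm": [d.stage_amounts_mm[1] for d in designs],
            "stage_III_mm": [d.stage_amounts_mm[2] for d in designs],
            "total_mm": [d.total_irrigation_mm for d in designs],
            "K2O_per_application_g": [d.k_dose_per_application_g for d in designs],
            "K2O_total_g": [d.total_k_g for d in designs],
        }
    )
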