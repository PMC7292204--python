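"""Pipeline configuration and the end-to-end run.

``run_all`` chains the stages: generate synthetic observations -> convert
assays to carbon pools -> invert conversion rates per treatment ->
forward-simulate the control as a conservation check -> factorial ANOVA
and LSD letters.  Every tabular artifact is CSV with a header row and
'.' decimal separator; a run log records package version, seed and stage
outcomes.  Identical config + seed gives byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_model import (
    CarbonPools,
    ConfigurationError,
    ModelConstants,
    RateSchedule,
    simulate_forward,
)
from .design import design_table
from .inversion import invert_rates
from .synthetic_data import (
    GeneratorConfig,
    TREATMENT_ORDER,
    generate_dataset,
    generate_growth,
    generate_temperature,
    truth_table,
)
from .treatment_stats import factorial_anova, lsd_from_anova
from .units import pools_table, read_observations

logger = logging.getLogger("tomsugar")

DEFAULT_RESPONSES = ("FW", "DW", "SSC", "STC", "frac_sol", "frac_sta", "frac_str")


def setup_logging(level: str = "INFO") -> None:
    """Route package logs to stderr with levels (idempotent)."""
    root = logging.getLogger("tomsugar")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
    root.setLevel(level.upper())


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips through JSON/YAML."""

    seed: int = 0
    outdir: str = "tomsugar_run"
    constants: dict = field(default_factory=dict)   # ModelConstants overrides
    generator: dict = field(default_factory=dict)   # GeneratorConfig overrides
    bandwidth: float = 0.6
    grid_step: float = 1.0
    k5: float | None = None                          # None -> ModelConstants.k5
    responses: tuple = DEFAULT_RESPONSES
    alpha: float = 0.05

    def model_constants(self) -> ModelConstants:
        return ModelConstants(**self.constants)

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(seed=self.seed, **self.generator)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["responses"] = list(self.responses)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "responses" in d:
            d["responses"] = tuple(d["responses"])
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        # YAML is a superset of JSON, so one loader covers both dialects
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)


def _fractions_per_observation(pools: pd.DataFrame) -> pd.DataFrame:
    total = pools["C_sol"] + pools["C_sta"] + pools["C_str"]
    out = pools.copy()
    out["frac_sol"] = pools["C_sol"] / total * 100.0
    out["frac_sta"] = pools["C_sta"] / total * 100.0
    out["frac_str"] = pools["C_str"] / total * 100.0
    return out


def run_stats(
    observations: pd.DataFrame,
    responses=DEFAULT_RESPONSES,
    factors=("water", "potassium", "stage"),
    alpha: float = 0.05,
    const: ModelConstants = ModelConstants(),
):
    """ANOVA tables and water-level LSD letters for the listed responses."""
    table = _fractions_per_observation(pools_table(observations, const=const))
    anova_rows, letter_rows = [], []
    for resp in responses:
        if resp not in table.columns:
            raise ConfigurationError(f"response column {resp} not in observations")
        res = factorial_anova(table, resp, factors)
        block = res.table.reset_index()
        block.insert(0, "response", resp)
        anova_rows.append(block)
        grouping = lsd_from_anova(table, resp, "water", res, alpha=alpha)
        for level in grouping.means.index:
            letter_rows.append(
                {
                    "response": resp,
                    "water": level,
                    "mean": grouping.means[level],
                    "letters": grouping.letters[level],
                }
            )
    return pd.concat(anova_rows, ignore_index=True), pd.DataFrame(letter_rows)


def run_all(config: PipelineConfig, observations_path=None) -> Path:
    """Execute every stage; returns the artifact directory.

    Stage failures abort with the stage name and offending file in the
    raised error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    const = config.model_constants()
    gen_cfg = config.generator_config()
    log_lines = [f"tomsugar {__version__}", f"numpy {np.__version__}, pandas {pd.__version__}",
                 f"seed {config.seed}"]

    def stage(name):
        logger.info("stage: %s", name)
        log_lines.append(f"stage {name}: ok")

    try:
        if observations_path is None:
            obs, truths = generate_dataset(gen_cfg, const)
            truth_table(truths).to_csv(outdir / "truth.csv", index=False)
            obs.to_csv(outdir / "observations.csv", index=False)
            stage("generate")
        else:
            obs = read_observations(observations_path)
            truths = None
            stage("load-observations")
    except Exception as e:
        raise RuntimeError(f"stage 'generate' failed ({observations_path or 'synthetic'}): {e}") from e

    design_table().to_csv(outdir / "design.csv", index=False)
    stage("design")

    env = generate_temperature(gen_cfg)
    k5 = config.k5 if config.k5 is not None else const.k5
    rate_frames = []
    try:
        for treatment, group in obs.groupby("treatment"):
            series, _ = invert_rates(
                group, env, const, k5=k5,
                bandwidth=config.bandwidth, grid_step=config.grid_step,
            )
            frame = series.to_frame()
            frame.insert(0, "treatment", treatment)
            rate_frames.append(frame)
        rates = pd.concat(rate_frames, ignore_index=True)
        rates.to_csv(outdir / "rates.csv", index=False)
        stage("invert")
    except Exception as e:
        raise RuntimeError(f"stage 'invert' failed (observations table): {e}") from e

    try:
        ck = rates[rates["treatment"] == "CK"].dropna(subset=["k3", "k5m"])
        growth = generate_growth("CK", "K0", gen_cfg)
        sched = RateSchedule(
            ck["DAA"].to_numpy(), ck["k3"].to_numpy(), ck["k5m"].to_numpy(), k5_per_day=k5
        )
        ck_pools = _fractions_per_observation(
            pools_table(obs[obs["treatment"] == "CK"], const=const)
        )
        first = ck_pools[ck_pools["DAA"] == ck_pools["DAA"].min()]
        # start the check from the mean observed pools nearest the rate window
        init = CarbonPools(
            float(first["C_sol"].mean()), float(first["C_sta"].mean()), float(first["C_str"].mean())
        )
        sim = simulate_forward(init, growth, env, sched, const)
        sim.to_frame().to_csv(outdir / "simulation.csv", index=False)
        defect = sim.conservation_defect()
        log_lines.append(f"conservation defect: {defect:.3e} g")
        stage("simulate-check")
    except Exception as e:
        raise RuntimeError(f"stage 'simulate-check' failed (rates.csv): {e}") from e

    try:
        anova, letters = run_stats(obs, config.responses, alpha=config.alpha, const=const)
        anova.to_csv(outdir / "anova.csv", index=False)
        letters.to_csv(outdir / "letters.csv", index=False)
        stage("stats")
    except Exception as e:
        raise RuntimeError(f"stage 'stats' failed (observations table): {e}") from e

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
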