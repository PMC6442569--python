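"""Schema-validated scenario configuration and the scenario runner.

A scenario file (YAML or JSON) describes one reproducible experiment: the
model variant, the market parameters, cost rates, horizon, and optional
migration / sweep / sensitivity / stochastic blocks. Unknown keys are
rejected so typos fail loudly before any computation. ``run_scenario``
executes the experiment and writes ``trajectory.csv``, ``costs.csv`` and
``summary.json`` (plus ``sweep.csv``/``sensitivity.csv``/``replicates.csv``
where applicable) into the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .calibration import calibrated_system
from .migration import MigrationParameters
from .model_core import MarketStateDisclosure, Parameters
from .r0 import r0_closed_form, threshold_classification
from .scenarios import sensitivity_oat, sweep_grid
from .simulate import (
    CostRates,
    average_cost_to_date,
    break_even_year,
    cost_series,
    disclosure_run,
    discount,
    savings_onset_year,
    simulate,
)
from .stochastic import gillespie_run

__all__ = ["ScenarioConfig", "load_config", "run_scenario"]

log = logging.getLogger("bedbugsim")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParameterConfig(_Strict):
    beta: Optional[float] = None
    gamma: Optional[float] = Field(default=None, gt=0)
    duration_months: Optional[float] = Field(default=None, gt=0)
    k: float = Field(default=0.3, ge=0, le=1)
    b: float = Field(default=1.3, ge=1)
    m: float = Field(default=0.5, gt=0)
    n: float = Field(default=6.0, gt=0)
    s: float = Field(default=0.5, ge=0, le=1)
    D: float = Field(default=1.0, gt=0)
    N: float = Field(default=1000.0, gt=0)
    p: float = Field(default=0.05, ge=0, lt=1)

    @model_validator(mode="after")
    def _gamma_xor_duration(self):
        if self.gamma is not None and self.duration_months is not None:
            raise ValueError("give gamma or duration_months, not both")
        return self

    def to_parameters(self) -> Parameters:
        gamma = self.gamma
        if gamma is None:
            gamma = (
                12.0 / self.duration_months
                if self.duration_months is not None
                else 2.0
            )
        return Parameters(
            beta=self.beta, gamma=gamma, k=self.k, b=self.b, m=self.m,
            n=self.n, s=self.s, D=self.D, N=self.N, p=self.p,
        )


class CostConfig(_Strict):
    c_trt: float = Field(default=1225.0, ge=0)
    c_tov: float = Field(default=1000.0, ge=0)
    c_vac: float = Field(default=1000.0, ge=0)
    discount_rate: float = Field(default=0.0, ge=0)

    def to_rates(self) -> CostRates:
        return CostRates(
            c_trt=self.c_trt, c_tov=self.c_tov, c_vac=self.c_vac,
            discount_rate=self.discount_rate,
        )


class MigrationConfig(_Strict):
    i: float = Field(ge=0, le=1)
    e: float = Field(ge=0, lt=1)

    def to_migration(self) -> MigrationParameters:
        return MigrationParameters(i=self.i, e=self.e)


class SweepConfig(_Strict):
    p_values: list[float]
    s_values: list[float]


class SensitivityConfig(_Strict):
    param: Literal["k", "duration", "b"]
    values: list[float]


class StochasticConfig(_Strict):
    seed: int = 0
    replicates: int = Field(default=10, ge=1)


class ScenarioConfig(_Strict):
    model: Literal["base", "disclosure", "migration", "stochastic"] = (
        "disclosure"
    )
    parameters: ParameterConfig = ParameterConfig()
    costs: CostConfig = CostConfig()
    horizon_years: int = Field(default=20, ge=1)
    report_step: float = Field(default=1.0, gt=0)
    migration: Optional[MigrationConfig] = None
    sweep: Optional[SweepConfig] = None
    sensitivity: Optional[SensitivityConfig] = None
    stochastic: Optional[StochasticConfig] = None
    output_dir: str = "."

    @model_validator(mode="after")
    def _blocks(self):
        if self.model == "migration" and self.migration is None:
            raise ValueError("migration model requires a migration block")
        return self


def load_config(path: str | Path) -> ScenarioConfig:
    """Parse and validate a YAML or JSON scenario file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return ScenarioConfig.model_validate(data)


def _summary(params, costs, rates):
    bd = r0_closed_form(params)
    cum_avg = average_cost_to_date(costs)
    return {
        "beta": params.beta,
        "r0": bd.r0,
        "r0_infectious_share": bd.infectious_share,
        "r0_relocation_share": bd.relocation_share,
        "threshold": threshold_classification(params),
        "break_even_year_annual": break_even_year(costs, "annual"),
        "break_even_year_cumulative": break_even_year(costs, "cumulative"),
        "savings_onset_year": savings_onset_year(costs),
        "average_cost_to_date": cum_avg.tolist(),
    }


def run_scenario(config: ScenarioConfig, output_dir: str | Path | None = None) -> dict:
    """Execute a validated scenario and write its outputs.

    Returns the summary dictionary that is also written to summary.json.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.parameters.to_parameters()
    rates = config.costs.to_rates()
    log.info("resolved parameters: %s", params)
    log.info("resolved cost rates: %s", rates)

    summary: dict = {"model": config.model}

    if config.model == "stochastic":
        sc = config.stochastic or StochasticConfig()
        system = calibrated_system(params=params)
        init = MarketStateDisclosure.from_base(
            _integer_equilibrium(system.equilibrium, params.N)
        )
        rows = []
        for r in range(sc.replicates):
            traj = gillespie_run(
                system.params, init, config.horizon_years,
                seed=sc.seed + r, report_step=config.report_step,
            )
            for t, state in zip(traj.yearly_times, traj.yearly_states):
                rows.append(
                    {"replicate": r, "year": t, "Sr": state[0],
                     "Ir": state[1], "Sv": state[2], "Iv": state[3],
                     "Svp": state[4]}
                )
        pd.DataFrame(rows).to_csv(out / "replicates.csv", index=False)
        summary.update({"beta": system.params.beta, "replicates": sc.replicates,
                        "seed": sc.seed})
    elif config.sweep is not None:
        res = sweep_grid(
            config.sweep.p_values, config.sweep.s_values,
            horizon=config.horizon_years, rates=rates, params=params,
        )
        res.table.to_csv(out / "sweep.csv", index=False)
        summary.update({"infeasible_cells": res.infeasible})
    elif config.sensitivity is not None:
        table = sensitivity_oat(
            config.sensitivity.param, config.sensitivity.values,
            horizon=config.horizon_years, rates=rates, params=params,
        )
        table.to_csv(out / "sensitivity.csv", index=False)
        summary.update({"param": config.sensitivity.param})
    else:
        mig = config.migration.to_migration() if config.migration else None
        traj_d, traj_b, costs = disclosure_run(
            params=params, rates=rates, horizon=config.horizon_years,
            migration=mig, report_step=config.report_step,
        )
        if rates.discount_rate > 0:
            costs = discount(costs, rates.discount_rate)
        traj_d.to_frame().to_csv(out / "trajectory.csv", index=False)
        pd.DataFrame([asdict(c) for c in costs]).to_csv(
            out / "costs.csv", index=False
        )
        summary.update(_summary(traj_d.params, costs, rates))
        summary["prevalence_by_year"] = traj_d.prevalence()[
            np.isclose(traj_d.times % 1.0, 0.0)
        ].tolist()

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _integer_equilibrium(eq, N):
    """Round the continuous equilibrium to integer counts summing to N."""
    vals = np.array([eq.Sr, eq.Ir, eq.Sv, eq.Iv])
    ints = np.floor(vals).astype(int)
    # distribute the remainder by largest fractional part
    rem = int(round(N)) - ints.sum()
    order = np.argsort(-(vals - ints))
    for j in range(rem):
        ints[order[j % 4]] += 1
    from .model_core import MarketStateBase

    return MarketStateBase(*[int(v) for v in ints])
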