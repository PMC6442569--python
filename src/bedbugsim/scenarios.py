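"""Policy-surface sweeps and one-at-a-time sensitivity analyses.

``sweep_grid`` maps the cost and prevalence consequences of disclosure over
the two parameters hardest to estimate and most variable between
municipalities: the baseline prevalence ``p`` and the renter selectivity
``s``. ``sensitivity_oat`` varies one uncertain transmission parameter at a
time (relocation probability ``k``, mean infestation duration ``1/gamma``,
vacancy multiplier ``b``) across its plausible range, recalibrating the
infectivity to the same baseline prevalence each time, so the analysis asks:
given a fixed observed prevalence, how wrong could the cost predictions be
if these inputs are wrong?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationError
from .model_core import Parameters
from .simulate import CostRates, disclosure_run

__all__ = ["SweepResult", "sweep_grid", "sensitivity_oat"]


@dataclass(frozen=True)
class SweepResult:
    """Long-format results of a (p, s) policy sweep.

    ``table`` has one row per (p, s, year) with columns ``p``, ``s``,
    ``year``, ``cost_total`` (annual, $/unit), ``cost_cumulative`` and
    ``prevalence`` (year-end). Cells where beta cannot be calibrated are
    listed in ``infeasible`` as (p, s) pairs and absent from the table.
    """

    p_values: np.ndarray
    s_values: np.ndarray
    table: pd.DataFrame
    infeasible: list[tuple[float, float]]

    def cell(self, p: float, s: float) -> pd.DataFrame:
        t = self.table
        return t[(np.isclose(t["p"], p)) & (np.isclose(t["s"], s))]


def sweep_grid(
    p_values: Sequence[float],
    s_values: Sequence[float],
    horizon: int = 20,
    rates: CostRates | None = None,
    params: Parameters | None = None,
) -> SweepResult:
    """Run the disclosure experiment over a (p, s) grid.

    For each cell, beta is calibrated to that baseline prevalence, both
    models are run from the corresponding equilibrium, and the annual total
    cost and year-end prevalence are recorded for years 1..``horizon``.
    ``p = 0`` cells are valid (disease-free market: all costs zero) and are
    run with beta = 0.
    """
    rates = rates or CostRates()
    base = params or Parameters()
    rows = []
    infeasible: list[tuple[float, float]] = []
    for p in p_values:
        for s in s_values:
            pp = base.replace(p=float(p), s=float(s), beta=None)
            try:
                traj_d, traj_b, costs = disclosure_run(
                    params=pp, rates=rates, horizon=horizon
                )
            except CalibrationError:
                infeasible.append((float(p), float(s)))
                continue
            prev = traj_d.prevalence()
            for rep in costs:
                rows.append(
                    {
                        "p": float(p),
                        "s": float(s),
                        "year": rep.year,
                        "cost_total": rep.total,
                        "cost_cumulative": rep.cumulative_total,
                        "prevalence": float(prev[traj_d.at_year(rep.year)]),
                    }
                )
    return SweepResult(
        p_values=np.asarray(p_values, dtype=float),
        s_values=np.asarray(s_values, dtype=float),
        table=pd.DataFrame(rows),
        infeasible=infeasible,
    )


_OAT_PARAMS = {"k", "duration", "b"}


def sensitivity_oat(
    param_name: str,
    values: Sequence[float],
    horizon: int = 20,
    rates: CostRates | None = None,
    params: Parameters | None = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity with beta recalibration.

    ``param_name`` is ``"k"`` (relocation-transmission probability),
    ``"duration"`` (mean infestation duration 1/gamma, in MONTHS), or
    ``"b"`` (vacancy multiplier). For each value the infectivity is
    recalibrated to the unchanged baseline prevalence, the policy experiment
    is rerun, and the final-year prevalence and savings are compared with
    the default run. Savings are the negative of the final-year ANNUAL total
    cost; cumulative savings are also reported for transparency.

    Returns a DataFrame with columns ``value``, ``prevalence``,
    ``annual_savings``, ``cumulative_savings``, ``prevalence_ratio``,
    ``annual_savings_ratio``, ``cumulative_savings_ratio``, ``feasible``.
    Ratios are relative to the default parameter set.
    """
    if param_name not in _OAT_PARAMS:
        raise ValueError(f"param_name must be one of {sorted(_OAT_PARAMS)}")
    rates = rates or CostRates()
    base = params or Parameters()

    def metrics(pp: Parameters):
        traj_d, _, costs = disclosure_run(
            params=pp, rates=rates, horizon=horizon
        )
        last = costs[-1]
        return (
            traj_d.prevalence_at(horizon),
            -last.total,
            -last.cumulative_total,
        )

    prev0, ann0, cum0 = metrics(base)
    rows = []
    for v in values:
        if param_name == "k":
            pp = base.replace(k=float(v), beta=None)
        elif param_name == "duration":
            pp = base.replace(gamma=12.0 / float(v), beta=None)
        else:
            pp = base.replace(b=float(v), beta=None)
        try:
            prev, ann, cum = metrics(pp)
        except CalibrationError:
            rows.append(
                {
                    "value": float(v), "prevalence": np.nan,
                    "annual_savings": np.nan, "cumulative_savings": np.nan,
                    "prevalence_ratio": np.nan,
                    "annual_savings_ratio": np.nan,
                    "cumulative_savings_ratio": np.nan,
                    "feasible": False,
                }
            )
            continue
        rows.append(
            {
                "value": float(v),
                "prevalence": prev,
                "annual_savings": ann,
                "cumulative_savings": cum,
                "prevalence_ratio": prev / prev0,
                "annual_savings_ratio": ann / ann0 if ann0 else np.nan,
                "cumulative_savings_ratio": cum / cum0 if cum0 else np.nan,
                "feasible": True,
            }
        )
    return pd.DataFrame(rows)
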