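"""Endemic equilibrium of the no-disclosure market and beta calibration.

The infectivity ``beta`` cannot be observed directly; field studies report
prevalence instead. Assuming the observed baseline prevalence ``p``
represents the market at its endemic equilibrium, the stationarity
conditions of the no-disclosure model pin down the equilibrium state in
closed form, and ``beta`` is then the unique value that makes that state a
fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import MarketStateBase, Parameters, relocation_fraction, rhs_base

__all__ = [
    "CalibrationError",
    "CalibratedSystem",
    "endemic_equilibrium_base",
    "calibrate_beta",
    "calibrate_beta_numeric",
    "calibrated_system",
]


class CalibrationError(ValueError):
    """The requested prevalence admits no valid equilibrium / positive beta."""


@dataclass(frozen=True)
class CalibratedSystem:
    """Parameter set with beta filled in, plus its endemic equilibrium."""

    params: Parameters
    equilibrium: MarketStateBase


def endemic_equilibrium_base(p: float, params: Parameters) -> MarketStateBase:
    """Closed-form endemic equilibrium of the no-disclosure model.

    Solves the stationarity conditions ``dIv = 0`` and ``dSv = 0`` together
    with the prevalence constraint ``(Ir + Iv)/N = p`` and conservation:

    * ``Ir* = N p (gamma + n) / (b m + gamma + n)``
    * ``Iv* = N p b m / (b m + gamma + n)``
    * ``Sr* = N/(m+n) * [n (1-p) - p m b gamma / (b m + gamma + n)]``
    * ``Sv* = N (1-p) - Sr*``

    beta does not appear: the infection flow is whatever balances the other
    flows, which is exactly what :func:`calibrate_beta` exploits.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p must be in [0, 1), got {p}")
    g, b, m, n, N = params.gamma, params.b, params.m, params.n, params.N
    denom = b * m + g + n
    Ir = N * p * (g + n) / denom
    Iv = N * p * b * m / denom
    Sr = (N / (m + n)) * (n * (1.0 - p) - p * m * b * g / denom)
    Sv = N * (1.0 - p) - Sr
    if Sr < 0 or Sv < 0:
        raise CalibrationError(
            f"no valid equilibrium at p={p}: Sr*={Sr:.4g}, Sv*={Sv:.4g}"
        )
    return MarketStateBase(Sr, Ir, Sv, Iv)


def calibrate_beta(p: float, params: Parameters, migration=None) -> float:
    """Infectivity that sustains prevalence ``p`` at equilibrium.

    Setting ``dIr = 0`` at the equilibrium state and solving for beta:

    ``beta = N/(Sr* Ir*) * [(gamma + b m) Ir* - k f* n Sv* - n Iv*]``

    with ``f* = b Ir*/(Sr* + b Ir*)``. Raises :class:`CalibrationError` when
    the bracket is non-positive, i.e. relocation transmission alone more
    than sustains ``p`` and no non-negative beta is consistent with it.

    When ``migration`` (a :class:`~bedbugsim.migration.MigrationParameters`)
    is given, the calibration is performed on the open-population
    no-disclosure system: the seeding fraction ``f*`` is replaced by the
    mover mixture ``(1-i) f* + i e_mover``, so that the market including
    immigration sits at the observed baseline prevalence before the policy.
    """
    if p <= 0.0:
        raise ValueError(f"p must be > 0 to calibrate beta, got {p}")
    eq = endemic_equilibrium_base(p, params)
    g, k, b, m, n, N = (
        params.gamma, params.k, params.b, params.m, params.n, params.N,
    )
    f = relocation_fraction(eq, params)
    if migration is not None:
        from .migration import external_mover_prevalence

        f = (1.0 - migration.i) * f + migration.i * external_mover_prevalence(
            migration.e, b
        )
    bracket = (g + b * m) * eq.Ir - k * f * n * eq.Sv - n * eq.Iv
    if bracket <= 0.0:
        raise CalibrationError(
            "calibration infeasible: relocation transmission alone sustains "
            f"p={p} (flow balance {bracket:.4g} <= 0)"
        )
    return (N / (eq.Sr * eq.Ir)) * bracket


def calibrate_beta_numeric(
    p: float,
    params: Parameters,
    beta_max: float = 100.0,
    tol: float = 1e-12,
) -> float:
    """Root-find beta such that the equilibrium state is stationary.

    Numeric cross-check of :func:`calibrate_beta`: finds the beta for which
    ``dIr/dt`` vanishes at the closed-form equilibrium. Intended for
    validation; the closed form is the production path.
    """
    eq = endemic_equilibrium_base(p, params)

    def residual(beta: float) -> float:
        return float(rhs_base(eq, params.replace(beta=beta))[1])

    lo, hi = 0.0, beta_max
    if residual(lo) >= 0.0:
        raise CalibrationError(
            f"calibration infeasible at p={p}: dIr/dt >= 0 already at beta=0"
        )
    return float(brentq(residual, lo, hi, xtol=tol))


def calibrated_system(
    p: float | None = None,
    params: Parameters | None = None,
    migration=None,
) -> CalibratedSystem:
    """Convenience: calibrate beta at ``p`` and package the fixed point.

    ``p`` defaults to ``params.p``; ``params`` defaults to the point
    estimates. ``migration`` switches the calibration to the open-population
    system (see :func:`calibrate_beta`).
    """
    params = params or Parameters()
    p = params.p if p is None else p
    # p = 0 is the disease-free market: no transmission to calibrate.
    beta = 0.0 if p == 0 else calibrate_beta(p, params, migration=migration)
    full = params.replace(beta=beta, p=p)
    return CalibratedSystem(params=full, equilibrium=endemic_equilibrium_base(p, full))
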