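"""Basic reproductive ratio of the infestation process.

R0 is the expected number of secondary infested units generated by one
infested unit introduced into an otherwise susceptible market. It factors
into (i) the rate at which an infested-occupied unit creates new
infestations at the disease-free market balance — infectious transmission of
rented units, ``beta * n/(n+m)``, plus relocation transmission of vacant
units, ``k*b*m`` — and (ii) the mean time a unit stays infested before being
treated, accounting for the vacancy detour slowed by renter selectivity.
Infestation persists when R0 > 1 and declines to zero when R0 < 1. R0 does
not depend on the disclosure period D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import Parameters

__all__ = [
    "R0Breakdown",
    "r0_closed_form",
    "r0_ngm_numeric",
    "threshold_classification",
]


@dataclass(frozen=True)
class R0Breakdown:
    """R0 with its transmission-route decomposition.

    ``infectious_share`` and ``relocation_share`` partition the
    new-infestation rate at the disease-free equilibrium between the two
    routes; ``mean_infectious_time`` (years) is the expected infested
    duration factor of R0.
    """

    r0: float
    infectious_share: float
    relocation_share: float
    mean_infectious_time: float


def r0_closed_form(params: Parameters) -> R0Breakdown:
    """Closed-form R0 from the next-generation expression.

    ``R0 = (beta*n/(n+m) + k*b*m) * (gamma + (1-s)*n)
           / (gamma * (gamma + b*m + (1-s)*n))``
    """
    beta = params.beta_required
    g, k, b, m, n, s = (
        params.gamma, params.k, params.b, params.m, params.n, params.s,
    )
    infectious_rate = beta * n / (n + m)
    relocation_rate = k * b * m
    new_infestation_rate = infectious_rate + relocation_rate
    mean_time = (g + (1.0 - s) * n) / (g * (g + b * m + (1.0 - s) * n))
    if new_infestation_rate > 0:
        rel_share = relocation_rate / new_infestation_rate
    else:
        rel_share = 0.0
    return R0Breakdown(
        r0=new_infestation_rate * mean_time,
        infectious_share=1.0 - rel_share,
        relocation_share=rel_share,
        mean_infectious_time=mean_time,
    )


def r0_ngm_numeric(params: Parameters) -> float:
    """R0 as the spectral radius of the next-generation matrix F V^-1.

    Built from the linearization of the disclosure model at the disease-free
    state (Sr = N n/(n+m), Sv = N m/(n+m)). New infestations enter Ir only:
    infectious transmission contributes ``beta*n/(n+m)`` and relocation
    seeding ``n*k*(b/Sr0)*Sv0 = k*b*m`` per infested-occupied unit. V
    collects the remaining linearized transitions between the infected
    compartments (Ir, Iv); the move-in flow Iv -> Ir relocates an existing
    infestation, so it lives in V, not F.
    """
    beta = params.beta_required
    g, k, b, m, n, s = (
        params.gamma, params.k, params.b, params.m, params.n, params.s,
    )
    if g == 0:
        raise ValueError("gamma = 0 makes the transition matrix singular")
    F = np.array(
        [[beta * n / (n + m) + k * b * m, 0.0],
         [0.0, 0.0]]
    )
    V = np.array(
        [[g + b * m, -(1.0 - s) * n],
         [-b * m, g + (1.0 - s) * n]]
    )
    ngm = F @ np.linalg.inv(V)
    return float(np.max(np.abs(np.linalg.eigvals(ngm))))


def threshold_classification(
    params: Parameters, atol: float = 1e-6
) -> str:
    """Long-run fate of infestation: ``"persists"``, ``"declines"``,
    or ``"boundary"`` when R0 is within ``atol`` of the threshold."""
    r0 = r0_closed_form(params).r0
    if abs(r0 - 1.0) <= atol:
        return "boundary"
    return "persists" if r0 > 1.0 else "declines"
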