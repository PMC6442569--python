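"""Compartmental model of bed bug spread through a rental market.

The unit of infection is a rental unit. Units are susceptible (bug-free) or
infested, and renter-occupied or vacant, giving four compartments in the
baseline market:

* ``Sr`` — susceptible-occupied
* ``Ir`` — infested-occupied
* ``Sv`` — susceptible-vacant
* ``Iv`` — infested-vacant

Under a disclosure policy a fifth compartment appears, ``Svp``
(susceptible-vacant-disclosed): a vacant unit that was treated but whose
infestation history must still be disclosed to prospective tenants for a
mandated period ``D``. Disclosure makes flagged units (``Iv`` and ``Svp``)
less attractive, reducing their move-in rate by a factor ``1 - s`` where
``s`` is the renter selectivity.

New infestations arise by two routes: *infectious transmission*, in which an
occupied unit picks up bugs at rate ``beta * Ir / N``, and *relocation
transmission*, in which a tenant arriving from a previously infested unit
seeds the vacant unit they move into with probability ``k``. The fraction of
movers originating in infested units is ``f = b*Ir / (Sr + b*Ir)``, where
``b >= 1`` is the factor by which infestation inflates the move-out rate.

All rates are per year; compartments are continuous (mean-field) occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

__all__ = [
    "Parameters",
    "MarketStateBase",
    "MarketStateDisclosure",
    "relocation_fraction",
    "rhs_base",
    "rhs_disclosure",
]


@dataclass(frozen=True)
class Parameters:
    """Model rates and policy knobs.

    Attributes
    ----------
    beta : float or None
        Infectivity (per year). Usually obtained from
        :func:`bedbugsim.calibration.calibrate_beta`; ``None`` until set.
    gamma : float
        Treatment rate (per year); ``1/gamma`` is the mean infestation
        duration.
    k : float
        Probability that a tenant arriving from an infested unit seeds a new
        infestation, in [0, 1].
    b : float
        Vacancy multiplier: factor (>= 1) by which infestation raises the
        move-out rate.
    m : float
        Baseline move-out rate (per year).
    n : float
        Move-in rate to vacant units (per year).
    s : float
        Renter selectivity in [0, 1]: fractional reduction in the move-in
        rate to disclosed (``Iv``/``Svp``) units. 0 = no behavioural change,
        1 = full quarantine.
    D : float
        Mandated disclosure period (years).
    N : float
        Total rental units.
    p : float
        Baseline (pre-policy) infestation prevalence, in [0, 1).
    """

    beta: float | None = None
    gamma: float = 2.0          # 1/gamma = 6 months
    k: float = 0.3
    b: float = 1.3
    m: float = 0.5
    n: float = 6.0
    s: float = 0.5
    D: float = 1.0
    N: float = 1000.0
    p: float = 0.05

    def __post_init__(self) -> None:
        if self.beta is not None and self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError(f"k must be in [0, 1], got {self.k}")
        if self.b < 1.0:
            raise ValueError(f"b must be >= 1, got {self.b}")
        if self.m <= 0:
            raise ValueError(f"m must be > 0, got {self.m}")
        if self.n <= 0:
            raise ValueError(f"n must be > 0, got {self.n}")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must be in [0, 1], got {self.s}")
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if self.N <= 0:
            raise ValueError(f"N must be > 0, got {self.N}")
        if not 0.0 <= self.p < 1.0:
            raise ValueError(f"p must be in [0, 1), got {self.p}")

    def replace(self, **changes) -> "Parameters":
        """Return a copy with the given fields replaced (validates again)."""
        return replace(self, **changes)

    @property
    def beta_required(self) -> float:
        if self.beta is None:
            raise ValueError("beta is not set; calibrate it first")
        return self.beta


@dataclass(frozen=True)
class MarketStateBase:
    """Compartment occupancies of the no-disclosure market (4 classes)."""

    Sr: float
    Ir: float
    Sv: float
    Iv: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Sr, self.Ir, self.Sv, self.Iv], dtype=float)

    @classmethod
    def from_array(cls, y) -> "MarketStateBase":
        return cls(*map(float, np.asarray(y)[:4]))

    @property
    def total(self) -> float:
        return self.Sr + self.Ir + self.Sv + self.Iv

    @property
    def infested(self) -> float:
        return self.Ir + self.Iv


@dataclass(frozen=True)
class MarketStateDisclosure:
    """Compartment occupancies under disclosure (5 classes, incl. Svp)."""

    Sr: float
    Ir: float
    Sv: float
    Iv: float
    Svp: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.Sr, self.Ir, self.Sv, self.Iv, self.Svp], dtype=float
        )

    @classmethod
    def from_array(cls, y) -> "MarketStateDisclosure":
        return cls(*map(float, np.asarray(y)[:5]))

    @classmethod
    def from_base(
        cls, state: MarketStateBase, Svp: float = 0.0
    ) -> "MarketStateDisclosure":
        """Lift a 4-compartment state into the disclosure model.

        The infested-vacant units stay in ``Iv`` (they are immediately
        disclosed); the disclosed-treated class starts at ``Svp``.
        """
        return cls(state.Sr, state.Ir, state.Sv, state.Iv, Svp)

    @property
    def total(self) -> float:
        return self.Sr + self.Ir + self.Sv + self.Iv + self.Svp

    @property
    def infested(self) -> float:
        return self.Ir + self.Iv


MarketState = Union[MarketStateBase, MarketStateDisclosure]


def _state_array(state) -> np.ndarray:
    if isinstance(state, (MarketStateBase, MarketStateDisclosure)):
        return state.as_array()
    return np.asarray(state, dtype=float)


def relocation_fraction(state, params: Parameters) -> float:
    """Fraction ``f`` of movers who come from infested units.

    ``f = b*Ir / (Sr + b*Ir)``: move-outs from infested units occur at rate
    ``b*m*Ir`` against ``m*Sr`` from susceptible units. Defined as 0 for an
    empty market (``Sr = Ir = 0``) so the flow terms stay finite everywhere.
    """
    y = _state_array(state)
    Sr, Ir = y[0], y[1]
    denom = Sr + params.b * Ir
    if denom <= 0.0:
        return 0.0
    return params.b * Ir / denom


def rhs_base(state, params: Parameters) -> np.ndarray:
    """Time derivative of the 4-compartment no-disclosure market.

    Flows: infectious transmission ``beta*Sr*Ir/N``; treatment ``gamma`` of
    both infested classes; move-ins ``n`` to all vacant units, seeding new
    infestations with probability ``k*f``; move-outs ``m`` (``b*m`` when
    infested). Returns ``d/dt [Sr, Ir, Sv, Iv]`` (per year); components sum
    to zero (units are conserved).
    """
    y = _state_array(state)
    Sr, Ir, Sv, Iv = y[0], y[1], y[2], y[3]
    beta = params.beta_required
    g, k, b, m, n, N = (
        params.gamma, params.k, params.b, params.m, params.n, params.N,
    )
    f = relocation_fraction(y, params)
    infection = beta * Sr * Ir / N
    dSr = -infection + g * Ir + n * (1.0 - k * f) * Sv - m * Sr
    dIr = infection + k * f * n * Sv + n * Iv - (g + b * m) * Ir
    dSv = m * Sr + g * Iv - n * Sv
    dIv = b * m * Ir - (g + n) * Iv
    return np.array([dSr, dIr, dSv, dIv])


def rhs_disclosure(state, params: Parameters) -> np.ndarray:
    """Time derivative of the 5-compartment market under disclosure.

    Relative to the base model: treated vacant units (``Iv`` -> ``Svp``)
    carry a disclosure flag for a mean period ``D`` (``Svp`` -> ``Sv`` at
    rate ``1/D``); move-ins to flagged units (``Iv``, ``Svp``) are slowed by
    the factor ``1 - s``. Relocation seeding with probability ``k*f``
    applies to move-ins into both susceptible-vacant classes. Returns
    ``d/dt [Sr, Ir, Sv, Iv, Svp]``; components sum to zero.
    """
    y = _state_array(state)
    return _rhs_disclosure_seeded(y, params, relocation_fraction(y, params))


def _rhs_disclosure_seeded(
    y: np.ndarray, params: Parameters, seed_fraction: float
) -> np.ndarray:
    """Disclosure RHS with the relocation-seeding fraction passed in.

    ``seed_fraction`` is the probability that an incoming tenant originates
    in an infested dwelling; the closed model uses ``f(t)``, the migration
    extension a mixture of ``f(t)`` and an external prevalence.
    """
    Sr, Ir, Sv, Iv, Svp = y[0], y[1], y[2], y[3], y[4]
    p = params
    beta = p.beta_required
    g, k, b, m, n, s, D, N = p.gamma, p.k, p.b, p.m, p.n, p.s, p.D, p.N
    kf = k * seed_fraction
    infection = beta * Sr * Ir / N
    dSr = (
        -infection + g * Ir
        + n * (1.0 - kf) * Sv
        + (1.0 - s) * n * (1.0 - kf) * Svp
        - m * Sr
    )
    dIr = (
        infection
        + n * kf * Sv
        + (1.0 - s) * n * kf * Svp
        + (1.0 - s) * n * Iv
        - (g + b * m) * Ir
    )
    dSv = m * Sr + Svp / D - n * Sv
    dIv = b * m * Ir - (g + (1.0 - s) * n) * Iv
    dSvp = g * Iv - ((1.0 - s) * n + 1.0 / D) * Svp
    return np.array([dSr, dIr, dSv, dIv, dSvp])
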