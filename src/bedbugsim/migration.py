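"""Open-population extension: tenants immigrating from external markets.

A fraction ``i`` of tenants moving into vacant units come from external
markets with a stable net infestation prevalence ``e``. Units do not migrate
— the market stays closed in units — but incoming tenants may seed
infestations at a rate reflecting where they came from. The probability that
an *internal* mover originates in an infested unit is ``f(t)``; for an
immigrant it is the external mover-weighted prevalence

    e_mover = b*e / (1 - e + b*e),

the analogue of ``f`` for a market sitting at prevalence ``e``: tenants
leaving infested units are overrepresented among movers by the vacancy
multiplier ``b``. Every move-in therefore seeds a new infestation with
probability ``k * [(1-i) * f(t) + i * e_mover]``. With ``i = 0`` the closed
disclosure model is recovered exactly.

Calibration note: in a market that genuinely receives immigrants, the
pre-policy endemic equilibrium already includes external seeding, so the
infectivity must be calibrated on the open-population system (pass the
migration parameters to :func:`bedbugsim.calibration.calibrate_beta`);
:func:`bedbugsim.simulate.disclosure_run` does this automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    Parameters,
    _rhs_disclosure_seeded,
    _state_array,
    relocation_fraction,
)

__all__ = ["MigrationParameters", "rhs_migration", "external_mover_prevalence"]


@dataclass(frozen=True)
class MigrationParameters:
    """Intermarket migration knobs.

    ``i``: fraction of incoming tenants from external markets, in [0, 1].
    ``e``: net infestation prevalence of the external markets, in [0, 1).
    """

    i: float = 0.0
    e: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.i <= 1.0:
            raise ValueError(f"i must be in [0, 1], got {self.i}")
        if not 0.0 <= self.e < 1.0:
            raise ValueError(f"e must be in [0, 1), got {self.e}")


def external_mover_prevalence(e: float, b: float) -> float:
    """Probability that an immigrant mover's previous unit was infested.

    ``b*e / (1 - e + b*e)``: mover-weighting of the external prevalence
    ``e``, mirroring ``f = b*Ir/(Sr + b*Ir)`` for internal movers.
    """
    return b * e / (1.0 - e + b * e)


def seeding_probability_fraction(
    state, params: Parameters, mig: MigrationParameters
) -> float:
    """Mixture origin-prevalence of movers: ``(1-i)*f(t) + i*e_mover``."""
    f = relocation_fraction(state, params)
    return (1.0 - mig.i) * f + mig.i * external_mover_prevalence(
        mig.e, params.b
    )


def rhs_migration(
    state, params: Parameters, mig: MigrationParameters
) -> np.ndarray:
    """Disclosure-model derivative with immigration of external tenants.

    Identical to :func:`bedbugsim.model_core.rhs_disclosure` except each
    move-in seeds a new infestation with probability
    ``k * [(1-i)*f(t) + i*e_mover]`` instead of ``k * f(t)``. Components sum
    to zero: only the seeding risk of incoming tenants changes, not the
    number of units.
    """
    y = _state_array(state)
    return _rhs_disclosure_seeded(
        y, params, seeding_probability_fraction(y, params, mig)
    )
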