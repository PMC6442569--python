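"""Event-driven stochastic counterpart of the disclosure model.

The mean-field ODE treats compartment occupancies as continuous; here the
same flows define a continuous-time Markov chain on integer unit counts,
simulated with the direct (Gillespie) method. Each flow term of the
disclosure model becomes an event with a propensity:

* infectious transmission  beta*Sr*Ir/N          (Sr -> Ir)
* move-out, susceptible    m*Sr                  (Sr -> Sv)
* move-out, infested       b*m*Ir                (Ir -> Iv)
* move-in to Sv            n*Sv                  (-> Ir w.p. k*f, else Sr)
* move-in to Svp           (1-s)*n*Svp           (-> Ir w.p. k*f, else Sr)
* move-in to Iv            (1-s)*n*Iv            (Iv -> Ir)
* treatment, occupied      gamma*Ir              (Ir -> Sr)
* treatment, vacant        gamma*Iv              (Iv -> Svp)
* disclosure expiry        Svp/D                 (Svp -> Sv)

Relocation seeding is resolved per move-in event by a single uniform draw
against ``k*f`` evaluated at the current state. The chain conserves N
exactly and converges to the ODE solution as N grows; near the persistence
threshold it exhibits demographic noise and a positive chance of eliminating
the infestation even when the deterministic model predicts persistence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import MarketStateDisclosure, Parameters, relocation_fraction

__all__ = ["EventTrajectory", "gillespie_run"]

EVENT_TYPES = (
    "infection",
    "move_out",
    "move_in_clean",
    "move_in_seeded",
    "treatment",
    "disclosure_expiry",
)

# compartment indices
_SR, _IR, _SV, _IV, _SVP = range(5)


@dataclass
class EventTrajectory:
    """Result of one stochastic run.

    ``yearly_times``/``yearly_states`` sample the chain on the reporting
    grid (state just before each report time); ``event_counts`` tallies the
    events by type over the whole run. When ``record_events`` was set, the
    full event log (``event_times``, ``event_states``) is kept — feasible
    for small markets only.
    """

    params: Parameters
    rng_seed: int
    yearly_times: np.ndarray
    yearly_states: np.ndarray  # (n_reports, 5) integer counts
    event_counts: dict[str, int]
    final_time: float
    event_times: np.ndarray | None = None
    event_states: np.ndarray | None = None

    def prevalence(self) -> np.ndarray:
        return (
            self.yearly_states[:, _IR] + self.yearly_states[:, _IV]
        ) / self.params.N


def gillespie_run(
    params: Parameters,
    init: MarketStateDisclosure,
    horizon: float,
    seed: int,
    report_step: float = 1.0,
    record_events: bool = False,
) -> EventTrajectory:
    """Simulate the disclosure-market jump process with the direct method.

    ``init`` must have integer counts summing to ``params.N``. The run is a
    deterministic function of ``seed``. If every propensity hits zero (all
    units susceptible-occupied can still move out, so this requires an
    empty market or degenerate rates) the final state is held to the
    horizon.
    """
    y = np.asarray(init.as_array(), dtype=np.int64)
    if np.any(np.asarray(init.as_array()) != y):
        raise ValueError("initial state must have integer counts")
    if y.sum() != int(params.N):
        raise ValueError("initial counts must sum to N")
    if np.any(y < 0):
        raise ValueError("initial counts must be nonnegative")

    beta = params.beta_required
    g, k, b, m, n, s, D, N = (
        params.gamma, params.k, params.b, params.m, params.n, params.s,
        params.D, params.N,
    )
    one_minus_s_n = (1.0 - s) * n
    rng = np.random.default_rng(seed)

    n_reports = int(round(horizon / report_step))
    report_times = np.arange(1, n_reports + 1) * report_step
    yearly_states = np.empty((n_reports + 1, 5), dtype=np.int64)
    yearly_states[0] = y
    next_report = 0

    counts = {name: 0 for name in EVENT_TYPES}
    log_t: list[float] = []
    log_y: list[np.ndarray] = []

    t = 0.0
    Sr, Ir, Sv, Iv, Svp = (int(v) for v in y)
    while True:
        a = (
            beta * Sr * Ir / N,     # 0 infection
            m * Sr,                 # 1 move-out S
            b * m * Ir,             # 2 move-out I
            n * Sv,                 # 3 move-in Sv
            one_minus_s_n * Svp,    # 4 move-in Svp
            one_minus_s_n * Iv,     # 5 move-in Iv
            g * Ir,                 # 6 treatment occupied
            g * Iv,                 # 7 treatment vacant
            Svp / D,                # 8 expiry
        )
        total = sum(a)
        if total <= 0.0:
            t = horizon
            break
        t += rng.exponential(1.0 / total)
        if t >= horizon:
            break
        # record reports passed before this event fires
        while next_report < n_reports and report_times[next_report] <= t:
            yearly_states[next_report + 1] = (Sr, Ir, Sv, Iv, Svp)
            next_report += 1
        u = rng.random() * total
        acc = 0.0
        for ev, rate in enumerate(a):
            acc += rate
            if u < acc:
                break
        if ev == 0:
            Sr -= 1; Ir += 1
            counts["infection"] += 1
        elif ev == 1:
            Sr -= 1; Sv += 1
            counts["move_out"] += 1
        elif ev == 2:
            Ir -= 1; Iv += 1
            counts["move_out"] += 1
        elif ev in (3, 4):
            f = relocation_fraction((Sr, Ir, Sv, Iv, Svp), params)
            seeded = rng.random() < k * f
            if ev == 3:
                Sv -= 1
            else:
                Svp -= 1
            if seeded:
                Ir += 1
                counts["move_in_seeded"] += 1
            else:
                Sr += 1
                counts["move_in_clean"] += 1
        elif ev == 5:
            Iv -= 1; Ir += 1
            counts["move_in_clean"] += 1
        elif ev == 6:
            Ir -= 1; Sr += 1
            counts["treatment"] += 1
        elif ev == 7:
            Iv -= 1; Svp += 1
            counts["treatment"] += 1
        else:
            Svp -= 1; Sv += 1
            counts["disclosure_expiry"] += 1
        if record_events:
            log_t.append(t)
            log_y.append(np.array((Sr, Ir, Sv, Iv, Svp), dtype=np.int64))
    # fill remaining reports with the final state
    while next_report < n_reports:
        yearly_states[next_report + 1] = (Sr, Ir, Sv, Iv, Svp)
        next_report += 1

    return EventTrajectory(
        params=params,
        rng_seed=seed,
        yearly_times=np.concatenate([[0.0], report_times]),
        yearly_states=yearly_states,
        event_counts=counts,
        final_time=min(t, horizon),
        event_times=np.asarray(log_t) if record_events else None,
        event_states=np.asarray(log_y) if record_events else None,
    )
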