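import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bedbugsim import (
    MarketStateBase,
    MarketStateDisclosure,
    MigrationParameters,
    Parameters,
    relocation_fraction,
    rhs_base,
    rhs_disclosure,
    rhs_migration,
    simulate,
)

N = 1000.0


def market_balance(params):
    """Disease-free split of N units between occupied and vacant."""
    n, m = params.n, params.m
    return params.N * n / (n + m), params.N * m / (n + m)


params_strategy = st.builds(
    Parameters,
    beta=st.floats(0.0, 10.0),
    gamma=st.floats(0.1, 10.0),
    k=st.floats(0.0, 1.0),
    b=st.floats(1.0, 5.0),
    m=st.floats(0.05, 5.0),
    n=st.floats(0.5, 20.0),
    s=st.floats(0.0, 1.0),
    D=st.floats(0.1, 5.0),
)

state5_strategy = st.lists(
    st.floats(0.0, N), min_size=5, max_size=5
).map(np.array)


class TestRelocationFraction:
    def test_zero_when_no_infested_occupied(self, default_params):
        assert relocation_fraction(
            MarketStateBase(900.0, 0.0, 90.0, 10.0), default_params
        ) == 0.0

    def test_symmetric_half_when_b_is_one(self):
        params = Parameters(b=1.0)
        state = MarketStateBase(400.0, 400.0, 100.0, 100.0)
        assert relocation_fraction(state, params) == pytest.approx(0.5)

    def test_value_at_default_equilibrium(self, calibrated_default):
        # b*Ir/(Sr + b*Ir) at the 5% equilibrium (Sr=875.77, Ir=46.24)
        f = relocation_fraction(
            calibrated_default.equilibrium, calibrated_default.params
        )
        assert f == pytest.approx(0.0642, abs=5e-4)

    def test_empty_market_defined_as_zero(self, default_params):
        assert relocation_fraction(
            MarketStateBase(0.0, 0.0, 500.0, 500.0), default_params
        ) == 0.0

    def test_increases_with_infested_occupied(self, default_params):
        fs = [
            relocation_fraction(
                MarketStateBase(800.0, ir, 50.0, 10.0), default_params
            )
            for ir in (10.0, 50.0, 200.0)
        ]
        assert fs == sorted(fs)


class TestBaseRHS:
    def test_disease_free_state_is_fixed_point(self, default_params):
        params = default_params.replace(beta=2.2572)
        occ, vac = market_balance(params)
        d = rhs_base(MarketStateBase(occ, 0.0, vac, 0.0), params)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_hand_evaluated_example(self, default_params):
        # each flow term evaluated by hand at (900, 50, 45, 5), f=0.06736
        params = default_params.replace(beta=2.2572)
        d = rhs_base(MarketStateBase(900.0, 50.0, 45.0, 5.0), params)
        assert d == pytest.approx([-187.03, 4.53, 190.00, -7.50], abs=0.01)

    def test_equilibrium_is_stationary(self, calibrated_default):
        d = rhs_base(
            calibrated_default.equilibrium, calibrated_default.params
        )
        assert np.max(np.abs(d)) < 1e-6 * calibrated_default.params.N


class TestDisclosureRHS:
    def test_disease_free_fixed_point(self, default_params):
        params = default_params.replace(beta=2.2572)
        occ, vac = market_balance(params)
        d = rhs_disclosure(
            MarketStateDisclosure(occ, 0.0, vac, 0.0, 0.0), params
        )
        assert np.allclose(d, 0.0, atol=1e-12)

    @given(y=state5_strategy)
    @settings(max_examples=50, deadline=None)
    def test_selectivity_zero_reduces_to_base_model(self, y):
        """With s=0 the (Sr, Ir, Sv+Svp, Iv) dynamics equal the base model."""
        params = Parameters(beta=2.2572, s=0.0)
        d5 = rhs_disclosure(y, params)
        d4 = rhs_base(np.array([y[0], y[1], y[2] + y[4], y[3]]), params)
        mapped = np.array([d5[0], d5[1], d5[2] + d5[4], d5[3]])
        assert np.allclose(mapped, d4, rtol=1e-12, atol=1e-9)


class TestConservation:
    @given(y=state5_strategy, params=params_strategy)
    @settings(max_examples=100, deadline=None)
    def test_all_rhs_conserve_units(self, y, params):
        tol = 1e-12 * params.N * 100
        assert abs(rhs_base(y[:4], params).sum()) < tol
        assert abs(rhs_disclosure(y, params).sum()) < tol
        mig = MigrationParameters(i=0.3, e=0.1)
        assert abs(rhs_migration(y, params, mig).sum()) < tol


class TestIntegratedInvariants:
    def test_positivity_over_twenty_years(self, calibrated_default):
        params = calibrated_default.params
        skewed = MarketStateDisclosure(10.0, 900.0, 0.0, 0.0, 90.0)
        traj = simulate("disclosure", params, skewed, horizon=20)
        assert traj.states.min() >= -1e-9 * params.N

    def test_per_unit_results_invariant_to_market_size(self, default_params):
        trajs = []
        for size in (1000.0, 1e6):
            params = default_params.replace(N=size, beta=2.2572)
            occ, vac = market_balance(params)
            init = MarketStateDisclosure(
                occ * 0.95, size * 0.04, vac * 0.95, size * 0.01, 0.0
            )
            trajs.append(
                simulate("disclosure", params, init, horizon=20).states
                / size
            )
        assert np.allclose(trajs[0], trajs[1], atol=1e-7)

    def test_selectivity_zero_trajectory_matches_base(self, calibrated_default):
        params = calibrated_default.params.replace(s=0.0)
        eq = calibrated_default.equilibrium
        base = simulate("base", params, eq, horizon=20)
        disc = simulate(
            "disclosure", params, MarketStateDisclosure.from_base(eq),
            horizon=20,
        )
        mapped = np.column_stack(
            [
                disc.states[:, 0],
                disc.states[:, 1],
                disc.states[:, 2] + disc.states[:, 4],
                disc.states[:, 3],
            ]
        )
        assert np.allclose(mapped, base.states, atol=1e-6 * params.N)


@pytest.mark.parametrize(
    "field,value",
    [("gamma", 0.0), ("k", 1.5), ("b", 0.9), ("s", -0.1), ("p", 1.0),
     ("m", 0.0), ("D", 0.0), ("beta", -1.0)],
)
def test_parameter_invariants_enforced(field, value):
    with pytest.raises(ValueError, match=field):
        Parameters(**{field: value})
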