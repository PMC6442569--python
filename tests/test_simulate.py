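import numpy as np
import pytest

from bedbugsim import (
    CostRates,
    MarketStateDisclosure,
    Parameters,
    annual_cost_components,
    average_cost_to_date,
    break_even_year,
    cost_series,
    disclosure_run,
    discount,
    savings_onset_year,
    simulate,
)


class TestIntegration:
    def test_base_model_holds_calibrated_prevalence(self, calibrated_default):
        traj = simulate(
            "base", calibrated_default.params,
            calibrated_default.equilibrium, horizon=20,
        )
        assert np.all(np.abs(traj.prevalence() - 0.05) < 1e-6)

    def test_units_conserved_at_every_report(self, default_run):
        traj_d, traj_b, _ = default_run
        for traj in (traj_d, traj_b):
            totals = traj.states.sum(axis=1)
            assert np.all(np.abs(totals - traj.N) < 1e-8 * traj.N)

    def test_report_grid_contains_integer_years(self, calibrated_default):
        traj = simulate(
            "disclosure", calibrated_default.params,
            MarketStateDisclosure.from_base(calibrated_default.equilibrium),
            horizon=5, report_step=0.25,
        )
        for year in range(6):
            assert traj.at_year(year) == 4 * year

    def test_accumulators_start_at_zero_and_never_decrease(self, default_run):
        traj_d, _, _ = default_run
        for acc in (
            traj_d.acc_treatments, traj_d.acc_turnovers, traj_d.acc_vacancy
        ):
            assert acc[0] == 0.0
            assert np.all(np.diff(acc) >= 0)

    def test_comparator_accumulators_match_equilibrium_rates(
        self, calibrated_default
    ):
        """At the fixed point the yearly event counts are analytic:
        gamma*(Ir+Iv)/N treatments, n*(Sv+Iv)/N turnovers, (Sv+Iv)/N
        vacant unit-years."""
        params = calibrated_default.params
        eq = calibrated_default.equilibrium
        traj = simulate("base", params, eq, horizon=20)
        trt = params.gamma * (eq.Ir + eq.Iv) / params.N
        tov = params.n * (eq.Sv + eq.Iv) / params.N
        vac = (eq.Sv + eq.Iv) / params.N
        for acc, per_year in (
            (traj.acc_treatments, trt),
            (traj.acc_turnovers, tov),
            (traj.acc_vacancy, vac),
        ):
            assert np.allclose(np.diff(acc), per_year, atol=1e-6)

    def test_prevalence_trajectory_reaches_paper_level(self, default_run):
        traj_d, _, _ = default_run
        # steady decline from 5% under s=0.5 disclosure
        prev = traj_d.prevalence()
        assert np.all(np.diff(prev) < 0)
        assert traj_d.prevalence_at(10) == pytest.approx(0.027, abs=0.001)

    def test_horizon_shorter_than_report_step_rejected(
        self, calibrated_default
    ):
        with pytest.raises(ValueError):
            simulate(
                "base", calibrated_default.params,
                calibrated_default.equilibrium, horizon=0.5, report_step=1.0,
            )

    def test_wrong_dimension_rejected(self, calibrated_default):
        with pytest.raises(ValueError):
            simulate(
                "base", calibrated_default.params,
                np.array([1.0, 2.0, 3.0]), horizon=5,
            )


class TestCostAccounting:
    def test_total_is_sum_of_components(self, default_run):
        _, _, costs = default_run
        for rep in costs:
            assert rep.total == rep.treatment + rep.turnover + rep.vacancy

    def test_no_selectivity_means_no_cost(self, calibrated_default):
        params = calibrated_default.params.replace(s=0.0)
        _, _, costs = disclosure_run(params=params, horizon=10)
        for rep in costs:
            assert rep.total == pytest.approx(0.0, abs=1e-4)

    def test_sign_structure_of_components(self, default_run):
        """Vacancy cost positive and declining over the first decade;
        treatment a saving from the first year on; eventual net savings."""
        _, _, costs = default_run
        vacancy = [rep.vacancy for rep in costs[:10]]
        assert all(v > 0 for v in vacancy)
        assert all(np.diff(vacancy[1:]) < 0)
        assert all(rep.treatment <= 0 for rep in costs)
        assert costs[19].total < 0

    def test_break_even_years(self, default_run):
        _, _, costs = default_run
        assert break_even_year(costs, "annual") == 5
        cum = break_even_year(costs, "cumulative")
        assert cum is not None and cum > 5
        assert savings_onset_year(costs) == 4

    def test_no_break_even_when_costs_never_negative(self):
        # costs are positive for the first few years at the defaults
        _, _, costs = disclosure_run(horizon=3)
        assert break_even_year(costs, "annual") is None
        assert savings_onset_year(costs) is None

    def test_break_even_rejects_empty_series(self):
        with pytest.raises(ValueError):
            break_even_year([], "annual")

    def test_average_cost_to_date_is_cumulative_mean(self, default_run):
        _, _, costs = default_run
        avg = average_cost_to_date(costs)
        assert avg[1] == pytest.approx(costs[1].cumulative_total / 2)
        # the headline number: ~$25/unit averaged over the first two years
        assert avg[1] == pytest.approx(25.0, abs=0.5)

    def test_mismatched_horizons_rejected(self, calibrated_default):
        params = calibrated_default.params
        eq = calibrated_default.equilibrium
        short = simulate("base", params, eq, horizon=2)
        long = simulate(
            "disclosure", params, MarketStateDisclosure.from_base(eq),
            horizon=10,
        )
        with pytest.raises(ValueError):
            annual_cost_components(long, short, CostRates(), year=5)


class TestDiscounting:
    def test_zero_rate_is_identity(self, default_run):
        _, _, costs = default_run
        assert discount(costs, 0.0) == list(costs)

    def test_definitional_factor(self, default_run):
        _, _, costs = default_run
        discounted = discount(costs, 0.05)
        for rep, drep in zip(costs, discounted):
            assert drep.total == pytest.approx(
                rep.total / 1.05 ** rep.year
            )

    def test_discounting_shrinks_late_savings_without_sign_change(
        self, default_run
    ):
        _, _, costs = default_run
        d = discount(costs, 0.05)
        assert d[19].total < 0
        assert abs(d[19].total) < abs(costs[19].total)

    def test_cumulative_recomputed_from_discounted_annuals(self, default_run):
        _, _, costs = default_run
        d = discount(costs, 0.03)
        assert d[-1].cumulative_total == pytest.approx(
            sum(rep.total for rep in d)
        )

    def test_negative_rate_rejected(self, default_run):
        _, _, costs = default_run
        with pytest.raises(ValueError):
            discount(costs, -0.01)


def test_rent_level_shifts_break_even(calibrated_default):
    """Higher monthly rent (vacancy cost) delays the conversion to savings."""
    _, _, costs_hi = disclosure_run(rates=CostRates(c_vac=2000.0), horizon=20)
    _, _, costs_lo = disclosure_run(rates=CostRates(c_vac=500.0), horizon=20)
    hi = break_even_year(costs_hi, "annual")
    lo = break_even_year(costs_lo, "annual")
    assert lo is not None and hi is not None
    assert lo <= 5 <= hi
    assert lo < hi
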