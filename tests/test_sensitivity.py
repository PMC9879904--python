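"""Moment matching, probabilistic sensitivity analysis, and the tornado."""

import numpy as np
import pandas as pd
import pytest

from oxmis_cea import (
    DistributionSpec,
    ParameterError,
    default_one_way_ranges,
    default_psa_specs,
    evaluate_strategy,
    incremental,
    make_clinical_strategy,
    make_oxmis_strategy,
    moment_match,
    one_way_sa,
    psa_run,
)
from oxmis_cea.sensitivity import VARIED_PARAMETERS, sample_parameter


def base_incremental(params):
    return incremental(
        evaluate_strategy(make_oxmis_strategy(params)),
        evaluate_strategy(make_clinical_strategy(params)),
        wtp=params.wtp_threshold,
    )


def fixed_specs(params):
    return tuple(DistributionSpec(name, "fixed", getattr(params, name))
                 for name in VARIED_PARAMETERS)


class TestMomentMatch:
    def test_gamma_closed_form(self):
        # shape = (m/s)^2, scale = s^2/m
        pars = moment_match("gamma", 1615.0, 323.0)
        assert pars["shape"] == pytest.approx(25.0)
        assert pars["scale"] == pytest.approx(64.6)

    def test_beta_closed_form(self):
        pars = moment_match("beta", 0.5, 0.25)
        assert pars["alpha"] == pytest.approx(1.5)
        assert pars["beta"] == pytest.approx(1.5)

    def test_fixed_is_a_point_mass(self):
        rng = np.random.default_rng(0)
        spec = DistributionSpec("cost_oxmis", "fixed", 57.0)
        assert all(sample_parameter(spec, rng) == 57.0 for _ in range(5))

    def test_beta_variance_beyond_feasible_rejected(self):
        with pytest.raises(ParameterError, match="variance"):
            moment_match("beta", 0.5, 0.6)

    @pytest.mark.parametrize("family, mean, sd", [
        ("beta", 0.25, 0.05), ("gamma", 1615.0, 323.0)])
    def test_sampled_moments_match_targets(self, family, mean, sd):
        rng = np.random.default_rng(42)
        spec = DistributionSpec("x", family, mean, sd)
        draws = np.array([sample_parameter(spec, rng) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(mean, rel=0.02)
        assert draws.std(ddof=1) == pytest.approx(sd, rel=0.05)

    def test_default_specs_use_beta_for_probabilities_gamma_for_costs(
            self, params):
        by_name = {s.parameter: s for s in default_psa_specs(params)}
        assert set(by_name) == set(VARIED_PARAMETERS)
        assert by_name["cost_hrm"].family == "gamma"
        assert by_name["p_high_oxmis"].family == "beta"
        assert by_name["utility_decrement_hrm"].family == "beta"
        assert by_name["cost_hrm"].sd == pytest.approx(0.2 * 1615)


class TestPSA:
    def test_degenerate_distributions_reproduce_base_case_exactly(
            self, params):
        base = base_incremental(params)
        res = psa_run(params, fixed_specs(params), n=100, seed=3)
        assert res.n_rejected == 0
        assert (res.draws["delta_cost"] == base.delta_cost).all()
        assert (res.draws["delta_qaly"] == base.delta_qaly).all()
        assert res.prop_dominant == 1.0

    def test_same_seed_gives_identical_results(self, params):
        specs = default_psa_specs(params)
        a = psa_run(params, specs, n=500, seed=11)
        b = psa_run(params, specs, n=500, seed=11)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        assert a.summary_dict() == b.summary_dict()
        assert a.ceac == b.ceac

    def test_quadrant_proportions_partition_the_draws(self, params):
        res = psa_run(params, default_psa_specs(params), n=2000, seed=5)
        total = (res.prop_dominant + res.prop_sw + res.prop_inferior
                 + res.prop_ne)
        assert total == pytest.approx(1.0, abs=1e-12)
        assert res.prop_cost_saving == pytest.approx(
            res.prop_dominant + res.prop_sw, abs=1e-12)

    def test_ceac_monotone_when_every_draw_gains_qalys(self, params):
        # vary only costs: delta_qaly is constant and positive, so the
        # acceptability curve can only rise with the threshold
        specs = tuple(
            s if s.parameter.startswith("cost_")
            else DistributionSpec(s.parameter, "fixed", s.mean)
            for s in default_psa_specs(params))
        res = psa_run(params, specs, n=1000, seed=9)
        assert (res.draws["delta_qaly"] > 0).all()
        values = [res.ceac[t] for t in sorted(res.ceac)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_mean_of_draws_consistent_with_base_case(self, params):
        """Model is nearly linear in each parameter, so the Monte Carlo
        mean incremental cost should sit within 3 standard errors of the
        incremental cost at the distribution means."""
        res = psa_run(params, default_psa_specs(params, cv=0.10),
                      n=4000, seed=17)
        dc = res.draws["delta_cost"]
        se = dc.std(ddof=1) / np.sqrt(len(dc))
        assert abs(dc.mean() - base_incremental(params).delta_cost) < 3 * se

    def test_sequential_scenario_selector(self, params):
        res = psa_run(params, fixed_specs(params), n=10, seed=1,
                      scenario="sequential")
        assert res.draws["delta_cost"].iloc[0] == pytest.approx(
            -249.69582, abs=1e-5)

    def test_unknown_scenario_rejected(self, params):
        with pytest.raises(ParameterError, match="scenario"):
            psa_run(params, fixed_specs(params), n=10, seed=1,
                    scenario="markov")


class TestTornado:
    def test_degenerate_range_has_zero_span_at_base_icer(self, params):
        base = base_incremental(params)
        rows = one_way_sa(params, {"cost_hrm": (1615.0, 1615.0)})
        assert len(rows) == 1
        assert rows[0].icer_at_low == pytest.approx(base.icer)
        assert rows[0].icer_at_high == pytest.approx(base.icer)
        assert rows[0].span == 0.0

    def test_rows_sorted_by_descending_span(self, params):
        rows = one_way_sa(params)
        spans = [r.span for r in rows]
        assert spans == sorted(spans, reverse=True)
        assert {r.parameter for r in rows} == set(VARIED_PARAMETERS)

    def test_icers_match_independent_recomputation(self, params):
        """Oracle check: recompute each end's ICER from path enumeration."""
        from test_tree import path_expectation

        rows = one_way_sa(params, {"p_high_oxmis": (0.20, 0.30)})
        (row,) = rows
        for value, icer in ((0.20, row.icer_at_low), (0.30, row.icer_at_high)):
            varied = params.replace(p_high_oxmis=value)
            cost_i, qaly_i, _ = path_expectation(make_oxmis_strategy(varied))
            cost_c, qaly_c, _ = path_expectation(make_clinical_strategy(varied))
            assert icer == pytest.approx(
                (cost_i - cost_c) / (qaly_i - qaly_c), rel=1e-12)

    def test_suicide_cost_has_negligible_influence(self, params):
        """Qualitative match to the published finding that the suicide
        event cost matters least."""
        rows = one_way_sa(params)
        assert rows[-1].parameter == "cost_suicide"

    def test_domain_violating_range_names_the_parameter(self, params):
        with pytest.raises(ParameterError, match="p_high_oxmis"):
            one_way_sa(params, {"p_high_oxmis": (0.1, 1.2)})
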