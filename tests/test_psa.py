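"""Distribution fitting and Monte Carlo probabilistic sensitivity analysis."""

import math

import numpy as np
import pytest

from ibdcea.cohort import SC, SC_NO_AVOIDANCE, SC_TM, expected_outcomes
from ibdcea.parameters import ModelParameters, ParameterEstimate
from ibdcea.psa import RANGE_TO_SD, ce_plane_export, fit_distribution, run_psa

SEED = 1


def _point_params(params):
    """Canonical values with every distribution collapsed to a point mass."""
    return ModelParameters(
        {
            e.name: ParameterEstimate(e.name, e.base, e.base, e.base, "point", e.units)
            for e in params
        }
    )


class TestFitDistribution:
    def test_normal_sd_from_range(self):
        est = ParameterEstimate("tm_encounters", 4.76, 4.046, 5.474, "normal")
        fit = fit_distribution(est)
        assert fit.args["mean"] == 4.76
        assert fit.args["sd"] == pytest.approx(0.36429, abs=1e-4)

    def test_beta_method_of_moments_against_brute_oracle(self):
        est = ParameterEstimate("p_comply", 0.59, 0.502, 0.679, "beta")
        fit = fit_distribution(est)
        # independent moment-matching oracle: alpha = m(m(1-m)/v - 1), etc.
        m = 0.59
        v = ((0.679 - 0.502) / RANGE_TO_SD) ** 2
        k = m * (1 - m) / v - 1
        assert fit.args["a"] == pytest.approx(m * k, rel=1e-12)
        assert fit.args["b"] == pytest.approx((1 - m) * k, rel=1e-12)
        assert fit.mean() == pytest.approx(m, abs=1e-12)

    def test_gamma_moments_recovered(self):
        est = ParameterEstimate("cost_hosp_uc", 7290, 6197, 8384, "gamma")
        fit = fit_distribution(est)
        sd = (8384 - 6197) / RANGE_TO_SD
        assert fit.mean() == pytest.approx(7290, rel=1e-12)
        var = fit.args["shape"] * fit.args["scale"] ** 2
        assert math.sqrt(var) == pytest.approx(sd, rel=1e-12)

    def test_lognormal_median_anchored(self):
        est = ParameterEstimate("rr_tm", 0.364, 0.310, 0.419, "lognormal")
        fit = fit_distribution(est)
        assert fit.median() == pytest.approx(0.364, abs=1e-9)
        assert fit.args["sigma"] == pytest.approx(
            (math.log(0.419) - math.log(0.310)) / RANGE_TO_SD, rel=1e-12
        )

    def test_point_and_zero_width_degenerate(self, params):
        assert fit_distribution(params.wtp).family == "point"
        # m_uc has a zero-width printed range: degenerates despite beta family
        fit = fit_distribution(params.m_uc)
        assert fit.family == "point"
        rng = np.random.default_rng(0)
        assert np.all(fit.sample(rng, 5) == 0.003)

    def test_beta_infeasible_moment_fit_names_parameter(self):
        est = ParameterEstimate("p_rare", 0.01, 0.0, 0.5, "beta")
        with pytest.raises(ValueError, match="p_rare"):
            fit_distribution(est)

    def test_samples_respect_support_and_range(self, params):
        rng = np.random.default_rng(SEED)
        for name in ("p_comply", "rr_avoid", "cost_hosp_cd", "tm_encounters"):
            est = params[name]
            fit = fit_distribution(est)
            x = fit.sample(rng, 2000, truncate=True)
            assert np.all(x >= est.low) and np.all(x <= est.high)
            lo, hi = fit.support
            y = fit.sample(rng, 2000, truncate=False)
            assert np.all(y > lo) and np.all(y < hi)


@pytest.fixture(scope="module")
def result(params):
    return run_psa(params, [SC_NO_AVOIDANCE, SC, SC_TM], n_draws=4000, seed=SEED)


class TestRunPsa:
    def test_seed_reproducibility_bit_for_bit(self, params):
        a = run_psa(params, [SC, SC_TM], n_draws=300, seed=SEED)
        b = run_psa(params, [SC, SC_TM], n_draws=300, seed=SEED)
        for name in a.parameter_draws:
            np.testing.assert_array_equal(a.parameter_draws[name],
                                          b.parameter_draws[name])
        for label in a.strategy_draws:
            for field in a.strategy_draws[label]:
                np.testing.assert_array_equal(a.strategy_draws[label][field],
                                              b.strategy_draws[label][field])
        assert a.summaries.equals(b.summaries)

    def test_point_mass_run_equals_base_case_exactly(self, params):
        pp = _point_params(params)
        res = run_psa(pp, [SC, SC_TM], n_draws=20, seed=SEED)
        for strat in (SC, SC_TM):
            base = expected_outcomes(params, strat)
            draws = res.strategy_draws[strat.label]
            assert np.all(draws["cost"] == base.cost)
            assert np.all(draws["qalys"] == base.qalys)
        s = res.summaries.set_index("comparison").loc["SC-TM vs SC"]
        assert s.delta_cost_sd == 0.0 and s.delta_qalys_sd == 0.0

    def test_quadrant_proportions_sum_to_one(self, result):
        s = result.summaries
        total = (
            s.prop_dominant + s.prop_trade_off_ne
            + s.prop_dominated + s.prop_trade_off_sw
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_ci_formula(self, result):
        s = result.summaries.iloc[0]
        half = 1.959963984540054 * s.delta_cost_sd / math.sqrt(s.n_draws)
        assert s.delta_cost_ci_low == pytest.approx(s.delta_cost_mean - half)
        assert s.delta_cost_ci_high == pytest.approx(s.delta_cost_mean + half)

    def test_sampled_parameter_means_converge(self, params):
        """Untruncated sample means match each fitted distribution's analytic
        mean within 3 SE; beta/gamma/normal means equal the base value."""
        res = run_psa(params, [SC], n_draws=10_000, seed=SEED, truncate=False)
        for name, draws in res.parameter_draws.items():
            fit = fit_distribution(params[name])
            se = draws.std(ddof=1) / math.sqrt(draws.size)
            assert abs(draws.mean() - fit.mean()) < 3 * se, name
            if fit.family in ("beta", "gamma", "normal"):
                assert fit.mean() == pytest.approx(params.value(name), rel=1e-9)

    def test_untruncated_means_match_multilinear_expectation(self, params):
        """The tree is multilinear in independent draws, so the PSA mean of
        every outcome equals the tree evaluated at per-parameter means."""
        res = run_psa(
            params, [SC_NO_AVOIDANCE, SC, SC_TM],
            n_draws=10_000, seed=SEED, truncate=False,
        )
        mean_values = {e.name: fit_distribution(e).mean() for e in params}
        from ibdcea.cohort import outcomes_from_values

        for strat in (SC_NO_AVOIDANCE, SC, SC_TM):
            _, _, cost, qalys = outcomes_from_values(mean_values, strat)
            draws = res.strategy_draws[strat.label]
            for field, expected in (("cost", cost), ("qalys", qalys)):
                x = draws[field]
                se = x.std(ddof=1) / math.sqrt(x.size)
                assert abs(x.mean() - expected) < 3 * se, (strat.label, field)

    def test_base_case_consistency_for_tm_comparison(self, params):
        res = run_psa(params, [SC, SC_TM], n_draws=10_000, seed=SEED, truncate=False)
        s = res.summaries.set_index("comparison").loc["SC-TM vs SC"]
        det = expected_outcomes(params, SC_TM).qalys - expected_outcomes(params, SC).qalys
        se = s.delta_qalys_sd / math.sqrt(s.n_draws)
        assert abs(s.delta_qalys_mean - det) < 3 * se

    def test_rejection_resampling_keeps_draws_valid(self, params):
        # push CD hospitalization near 1 so avoidance can overflow it
        p = ModelParameters(
            {**params.estimates,
             "h_cd": ParameterEstimate("h_cd", 0.97, 0.95, 0.99, "beta")}
        )
        res = run_psa(p, [SC_NO_AVOIDANCE, SC], n_draws=400, seed=SEED)
        assert res.n_rejected > 0
        assert np.all(res.strategy_draws["SC"]["hosp"] <= 1.0)

    def test_bad_inputs(self, params):
        with pytest.raises(ValueError):
            run_psa(params, [SC], n_draws=0, seed=SEED)
        with pytest.raises(ValueError):
            run_psa(params, [], n_draws=10, seed=SEED)


class TestCePlane:
    def test_row_count_and_metadata(self, params):
        res = run_psa(params, [SC, SC_TM], n_draws=50, seed=SEED)
        df = ce_plane_export(res, "SC-TM vs SC")
        assert len(df) == 50
        assert df.attrs["wtp"] == res.wtp
        assert set(df.columns) == {"draw", "delta_qalys", "delta_cost"}

    def test_point_mass_rows_identical(self, params):
        res = run_psa(_point_params(params), [SC, SC_TM], n_draws=10, seed=SEED)
        df = ce_plane_export(res, "SC-TM vs SC")
        assert df.delta_cost.nunique() == 1 and df.delta_qalys.nunique() == 1

    def test_unknown_comparison_rejected(self, params):
        res = run_psa(params, [SC, SC_TM], n_draws=10, seed=SEED)
        with pytest.raises(KeyError):
            ce_plane_export(res, "nope")
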