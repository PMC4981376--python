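"""Distribution fitting, tornado ranking, and PSA reproducibility."""
import numpy as np
import pandas as pd
import pytest

from rhdcea import (CostSet, ParameterEstimate, ParameterSet, ValidationError,
                    evaluate_scenario, fit_dirichlet_group, fit_distribution,
                    run_psa, sample_inputs, tornado)
from rhdcea.sensitivity import _build_sampler

N_MC = 100_000


def degenerate_inputs(params, costs):
    """Collapse every bound onto the base value (Dirac distributions)."""
    p = ParameterSet([e.replace(low=e.base, high=e.base) for e in params.values()])
    c = CostSet([i.replace(low=i.base, high=i.base) for i in costs.values()])
    return p, c


class TestFitDistribution:
    def test_symmetric_beta_has_equal_shapes(self):
        est = ParameterEstimate(name="p", base=0.5, low=0.25, high=0.75,
                                family="beta")
        fit = fit_distribution(est)
        assert fit.family == "beta"
        assert fit.params["a"] == pytest.approx(fit.params["b"])

    def test_lognormal_median_matches_relative_risk(self, params, rng):
        # SP risk reduction 0.450 (0.220-0.920): median of 1-RR should be 0.55
        fit = fit_distribution(params["rr_secondary_prevention"])
        draws = fit.sample(rng, size=N_MC)
        assert np.median(1 - draws) == pytest.approx(0.55, abs=0.005)
        assert np.all(draws > 0) and np.all(draws < 1)

    def test_gamma_age_mean_matches_base(self, params, rng):
        fit = fit_distribution(params["age_first_arf"])
        draws = fit.sample(rng, size=N_MC)
        sd = draws.std() / np.sqrt(N_MC)
        assert abs(draws.mean() - 8.0) < 3 * sd + 1e-3
        assert np.all(draws >= 0)

    def test_cost_gamma_mean_matches_base(self, costs, rng):
        fit = fit_distribution(costs["cost_sp_program"])
        draws = fit.sample(rng, size=N_MC)
        sd = draws.std() / np.sqrt(N_MC)
        assert abs(draws.mean() - 2226.59) < 3 * sd

    def test_infeasible_beta_falls_back_to_uniform(self):
        # mean near 0 with wide bounds makes the beta moments infeasible
        est = ParameterEstimate(name="p", base=0.01, low=0.0, high=0.9,
                                family="beta")
        with pytest.warns(RuntimeWarning, match="uniform"):
            fit = fit_distribution(est)
        assert fit.family == "uniform"

    def test_degenerate_bounds_sample_exactly(self, rng):
        est = ParameterEstimate(name="p", base=0.3, low=0.3, high=0.3,
                                family="beta")
        fit = fit_distribution(est)
        assert np.all(fit.sample(rng, size=10) == 0.3)


class TestDirichletGroups:
    def group(self, params, name):
        return sorted(params.groups()[name], key=lambda e: e.name)

    def test_samples_lie_on_the_simplex(self, params, rng):
        fit = fit_dirichlet_group(self.group(params, "arf_first_exits"))
        draws = fit.sample(rng, size=10_000)
        # members plus the implicit remainder sum to one
        assert np.all(draws >= 0) and np.all(draws.sum(axis=1) <= 1 + 1e-12)

    def test_component_means_match_base_shares(self, params, rng):
        members = self.group(params, "arf_first_exits")
        fit = fit_dirichlet_group(members)
        draws = fit.sample(rng, size=N_MC)
        for j, est in enumerate(members):
            se = draws[:, j].std() / np.sqrt(N_MC)
            assert abs(draws[:, j].mean() - est.base) < 3 * se + 1e-4

    def test_structural_zero_stays_zero(self, params, rng):
        members = self.group(params, "hf_exits")
        fit = fit_dirichlet_group(members)
        draws = fit.sample(rng, size=1000)
        j = [e.name for e in members].index("hf_remission")
        assert np.all(draws[:, j] == 0.0)

    def test_large_concentration_collapses_to_base(self, params, rng):
        members = self.group(params, "arf_first_exits")
        fit = fit_dirichlet_group(members)
        fit = type(fit)(family="dirichlet", names=fit.names, params={
            "alpha": fit.params["alpha"] / fit.params["alpha"].sum() * 1e8})
        draws = fit.sample(rng, size=200)
        for j, est in enumerate(members):
            assert np.allclose(draws[:, j], est.base, atol=1e-3)

    def test_overfull_group_rejected(self):
        a = ParameterEstimate(name="a", base=0.7, low=0.6, high=0.8,
                              family="dirichlet", competing_group="g")
        b = ParameterEstimate(name="b", base=0.5, low=0.4, high=0.6,
                              family="dirichlet", competing_group="g")
        with pytest.raises(ValidationError, match="'g'"):
            fit_dirichlet_group([a, b])


class TestSampleInputs:
    def test_sampled_probabilities_respect_domains(self, params, costs, rng):
        fits = _build_sampler(params, costs)
        for _ in range(200):
            p, c, draw = sample_inputs(params, costs, rng, fits)
            for name in params:
                est = p[name]
                if est.kind in ("probability", "disability_weight"):
                    assert 0 <= est.base <= 1
                elif est.kind == "risk_reduction":
                    assert 0 < est.base < 1
                else:
                    assert est.base >= 0
            for name in c:
                assert c[name].base >= 0


class TestTornado:
    def test_sp_top_input_is_the_sp_risk_reduction(self, model):
        scen = next(s for s in model.scenarios if s.intervention == "SP")
        df = model.tornado(scen)
        assert df.iloc[0]["input"] == "rr_secondary_prevention"
        assert bool(df.iloc[0]["top10"])

    def test_fixed_input_has_zero_impact(self, model):
        scen = next(s for s in model.scenarios if s.intervention == "SP")
        df = model.tornado(scen).set_index("input")
        # the HF-remission row is pinned at 0.000 (0.000-0.000)
        assert df.loc["hf_remission", "impact"] == 0.0
        positive = df["impact"].dropna()
        assert df.loc["hf_remission", "rank"] > positive[positive > 0].index.size

    def test_impacts_match_direct_reevaluation(self, params, costs, life68,
                                               scenarios):
        scen = scenarios[1]
        df = tornado(params, costs, life68, scen).set_index("input")
        for name in ("rr_secondary_prevention", "cost_sp_program"):
            if name in params:
                lo = evaluate_scenario(
                    params.with_values({name: params[name].low}), costs,
                    life68, scen).icer.value
                hi = evaluate_scenario(
                    params.with_values({name: params[name].high}), costs,
                    life68, scen).icer.value
            else:
                lo = evaluate_scenario(
                    params, costs.with_values({name: costs[name].low}),
                    life68, scen).icer.value
                hi = evaluate_scenario(
                    params, costs.with_values({name: costs[name].high}),
                    life68, scen).icer.value
            assert df.loc[name, "impact"] == pytest.approx(abs(hi - lo))

    def test_ranking_invariant_to_input_order(self, params, costs, life68,
                                              scenarios):
        scen = scenarios[0]
        base = tornado(params, costs, life68, scen)
        shuffled = ParameterSet(list(params.values())[::-1])
        again = tornado(shuffled, costs, life68, scen)
        pd.testing.assert_frame_equal(base, again)

    def test_discount_rate_is_among_inputs(self, model):
        df = model.tornado("PP")
        assert "discount_rate" in set(df["input"])


class TestRunPsa:
    def test_same_seed_reproduces_bitwise(self, params, costs, life68,
                                          scenarios):
        a = run_psa(params, costs, life68, scenarios[:2], n_trials=15, seed=42)
        b = run_psa(params, costs, life68, scenarios[:2], n_trials=15, seed=42)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        for name in a.results:
            assert np.array_equal(a.results[name], b.results[name])

    def test_different_seeds_differ(self, params, costs, life68, scenarios):
        a = run_psa(params, costs, life68, scenarios[:1], n_trials=5, seed=1)
        b = run_psa(params, costs, life68, scenarios[:1], n_trials=5, seed=2)
        assert not a.samples.equals(b.samples)

    def test_degenerate_psa_collapses_to_deterministic(self, params, costs,
                                                       life68, scenarios):
        p, c = degenerate_inputs(params, costs)
        psa = run_psa(p, c, life68, scenarios, n_trials=1, seed=7)
        for scen in scenarios:
            det = evaluate_scenario(params, costs, life68, scen)
            dc, de = psa.results[scen.name][0]
            assert dc == pytest.approx(det.delta_cost, abs=1e-9)
            assert de == pytest.approx(det.delta_effect, abs=1e-9)

    def test_summary_reports_credible_intervals(self, params, costs, life68,
                                                scenarios):
        psa = run_psa(params, costs, life68, scenarios[:1], n_trials=25, seed=3)
        summary = psa.summary()
        assert {"icer_2.5%", "icer_97.5%", "icer_of_means"} <= set(summary.columns)
        assert summary.loc[0, "icer_2.5%"] <= summary.loc[0, "icer_97.5%"]

    def test_invalid_trial_count_rejected(self, params, costs, life68,
                                          scenarios):
        with pytest.raises(ValidationError):
            run_psa(params, costs, life68, scenarios[:1], n_trials=0, seed=0)
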