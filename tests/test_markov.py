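"""Markov machinery: coverage weighting, decay, matrices, and traces."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhdcea import (LifeTable, State, ValidationError, build_matrix,
                    build_transition_matrices, decayed_probability,
                    effective_probability, run_cohort, weighted_transition)
from rhdcea.markov import N_STATES, CohortTrace
from rhdcea.parameters import ScenarioConfig

unit = st.floats(min_value=0.0, max_value=1.0)


class TestWeightedTransition:
    def test_reproduces_partial_coverage_arithmetic(self):
        # 10% covered at 80% vs 0% uncovered -> 8%; 95% covered -> 76%
        assert weighted_transition(0.80, 0.0, 0.10) == pytest.approx(0.08)
        assert weighted_transition(0.80, 0.0, 0.95) == pytest.approx(0.76)

    @settings(derandomize=True, max_examples=50)
    @given(tp=unit, c=unit)
    def test_equal_probabilities_make_coverage_irrelevant(self, tp, c):
        assert weighted_transition(tp, tp, c) == pytest.approx(tp)

    @settings(derandomize=True, max_examples=50)
    @given(on=unit, off=unit, c=unit)
    def test_linear_interpolation_between_arms(self, on, off, c):
        f0 = weighted_transition(on, off, 0.0)
        f1 = weighted_transition(on, off, 1.0)
        assert f0 == off and f1 == on
        expected = (1 - c) * f0 + c * f1
        assert weighted_transition(on, off, c) == pytest.approx(expected)

    def test_rejects_out_of_range_arguments(self):
        with pytest.raises(ValidationError):
            weighted_transition(1.2, 0.0, 0.5)
        with pytest.raises(ValidationError):
            weighted_transition(0.5, 0.0, -0.1)


class TestDecay:
    def test_no_time_elapsed_returns_baseline(self):
        assert decayed_probability(0.00045, 0) == 0.00045

    def test_ten_year_decay(self):
        assert decayed_probability(0.00045, 10) == pytest.approx(
            0.00045 * np.exp(-1.0))

    @settings(derandomize=True, max_examples=50)
    @given(tp=unit, t1=st.floats(0, 50), t2=st.floats(0, 50))
    def test_monotone_in_elapsed_time(self, tp, t1, t2):
        lo, hi = sorted([t1, t2])
        assert decayed_probability(tp, hi) <= decayed_probability(tp, lo)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            decayed_probability(0.1, -1)


class TestEffectiveProbability:
    def test_full_coverage_applies_full_risk_reduction(self):
        assert effective_probability(0.113, 0.45, 1.0) == pytest.approx(0.06215)

    def test_zero_coverage_leaves_probability_unchanged(self):
        assert effective_probability(0.113, 0.45, 0.0) == pytest.approx(0.113)

    def test_perfect_intervention_eliminates_transition(self):
        assert effective_probability(0.4, 1.0, 1.0) == 0.0


class TestBuildMatrix:
    @pytest.mark.parametrize("coverage", [0.0, 0.1, 0.5, 0.95, 1.0])
    def test_rows_are_stochastic_at_every_age(self, params, life68, coverage):
        ages = np.arange(0, 101)
        M = build_transition_matrices(params, life68, ages, coverage)
        assert np.allclose(M.sum(axis=2), 1.0, atol=1e-12)
        assert np.all(M >= 0) and np.all(M <= 1)

    def test_absorbing_rows_are_unit_vectors(self, params, life68):
        M = build_matrix(params, life68, 8, 0.0)
        for s in (State.DEAD_DISEASE, State.DEAD_OTHER):
            expected = np.zeros(N_STATES)
            expected[s] = 1.0
            assert np.array_equal(M[s], expected)

    def test_first_arf_probability_inside_window(self, params, life68):
        M = build_matrix(params, life68, 8, 0.0)
        q = life68.q[8]
        assert M[State.WELL, State.ARF_FIRST] == pytest.approx(
            0.00045 * (1 - q), abs=1e-12)

    def test_first_arf_probability_zero_before_window(self, params, life68):
        M = build_matrix(params, life68, 3, 0.0)
        assert M[State.WELL, State.ARF_FIRST] == 0.0

    def test_first_arf_probability_decays_after_window(self, params, life68):
        M = build_matrix(params, life68, 20, 0.0)
        q = life68.q[20]
        expected = 0.00045 * np.exp(-0.1 * (20 - 14)) * (1 - q)
        assert M[State.WELL, State.ARF_FIRST] == pytest.approx(expected, abs=1e-15)

    def test_surgery_reduces_hf_death_at_full_coverage(self, params, life68):
        # 0.125 * (1 - 0.800) = 0.025 before background-mortality composition
        M = build_matrix(params, life68, 30, {"PP": 0, "SP": 0, "VS": 1.0})
        q = life68.q[30]
        assert M[State.SEVERE_HF, State.DEAD_DISEASE] == pytest.approx(
            0.025 * (1 - q), abs=1e-12)

    def test_no_remission_from_heart_failure_without_surgery(self, params, life68):
        M = build_matrix(params, life68, 30, 0.0)
        assert M[State.SEVERE_HF, State.RHD] == 0.0

    def test_arf_tunnel_states_empty_each_cycle(self, params, life68):
        M = build_matrix(params, life68, 10, 0.2)
        assert M[State.ARF_FIRST, State.ARF_FIRST] == 0.0
        assert M[State.ARF_RECUR, State.ARF_RECUR] == 0.0


class TestRunCohort:
    def test_trace_matches_matrix_product_oracle(self, params, life68):
        scen = ScenarioConfig(name="sp", intervention="SP", coverage_ante=0.1,
                              coverage_post=0.92, cycles=40)
        trace = run_cohort(params, life68, scen, 0.5)
        ages = trace.start_age + np.arange(scen.cycles)
        Ms = build_transition_matrices(params, life68, ages,
                                       scen.coverage_map(0.5))
        occ = np.zeros(N_STATES)
        occ[State.RF_REMISSION] = 1.0
        for k in range(scen.cycles):
            assert np.allclose(trace.occupancy[k], occ, atol=1e-12)
            occ = occ @ Ms[k]
        assert np.allclose(trace.occupancy[-1], occ, atol=1e-12)

    def test_zero_hazards_freeze_the_cohort(self, params, life68):
        zeros = {name: 0.0 for name in params
                 if params[name].kind == "probability"}
        frozen = params.with_values(zeros)
        lt = LifeTable.from_mortality(
            np.concatenate([np.zeros(150), [1.0]]))
        scen = ScenarioConfig(name="pp", intervention="PP", coverage_ante=0.1,
                              coverage_post=0.7, cycles=100)
        trace = run_cohort(frozen, lt, scen, 0.1)
        assert np.all(trace.occupancy[:, State.WELL] == 1.0)

    def test_certain_background_death_empties_cohort_at_cycle_one(self, params):
        lt = LifeTable(q=np.ones(102), e=np.full(102, 0.5))
        scen = ScenarioConfig(name="pp", intervention="PP", coverage_ante=0.1,
                              coverage_post=0.7, cycles=10)
        trace = run_cohort(params, lt, scen, 0.1)
        assert np.all(trace.occupancy[1:, State.DEAD_OTHER] == 1.0)

    def test_mass_conservation_and_monotone_death(self, model):
        for scen in model.scenarios:
            trace = run_cohort(model.parameters, model.life_table, scen,
                               scen.coverage_post)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            for s in (State.DEAD_DISEASE, State.DEAD_OTHER):
                assert np.all(np.diff(trace.occupancy[:, s]) >= -1e-12)

    def test_disease_deaths_non_increasing_in_coverage(self, model):
        for scen in model.scenarios:
            deaths = []
            for cov in np.arange(0, 1.01, 0.1):
                trace = run_cohort(model.parameters, model.life_table, scen,
                                   float(cov))
                deaths.append(trace.occupancy[-1, State.DEAD_DISEASE])
            assert np.all(np.diff(deaths) <= 1e-12)


class TestCohortTraceInvariants:
    def test_rejects_non_conserving_occupancy(self):
        occ = np.zeros((3, N_STATES))
        occ[:, State.WELL] = [1.0, 0.9, 1.0]
        with pytest.raises(ValidationError, match="sum to 1"):
            CohortTrace(occupancy=occ, start_age=0)

    def test_rejects_shrinking_absorbing_state(self):
        occ = np.zeros((3, N_STATES))
        occ[:, State.DEAD_DISEASE] = [0.5, 0.4, 0.4]
        occ[:, State.WELL] = [0.5, 0.6, 0.6]
        with pytest.raises(ValidationError, match="non-decreasing"):
            CohortTrace(occupancy=occ, start_age=0)

    def test_export_includes_cycle_and_age_columns(self, params, life68, tmp_path):
        scen = ScenarioConfig(name="vs", intervention="VS_refer",
                              coverage_ante=0.1, coverage_post=0.95, cycles=5)
        trace = run_cohort(params, life68, scen, 0.95)
        df = trace.to_frame()
        assert list(df.columns[:2]) == ["cycle", "age"]
        assert df["age"].iloc[0] == trace.start_age
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        assert path.exists()
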