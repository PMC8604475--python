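"""Cohort engine: normalization, traces, QALY and cost accumulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from markovcea import (
    CohortTrace,
    ModelSpec,
    TransitionModel,
    UtilitySet,
    accumulate_costs,
    accumulate_qalys,
    normalize_transition_rows,
    run_cohort,
)
from markovcea.markov import CYCLE_LENGTH_YEARS, EXCLUDE_INITIAL, HealthState

from conftest import random_transition_matrix

CYC = CYCLE_LENGTH_YEARS
BASE_UTILITIES = UtilitySet([0.77, 0.63, 0.44], [0.1, 0.1, 0.1])


def vi_transition_model():
    return TransitionModel.from_unnormalized(
        [[1, 0, 0], [0, 1, 0], [0.19, 0.63, 0.19]],
        [[0.95, 0.05, 0], [0.05, 0.95, 0], [0, 0.05, 0.95]],
    )


def tdcs_transition_model():
    return TransitionModel.from_unnormalized(
        [[1, 0, 0], [0, 1, 0], [0.1, 0.5, 0.4]],
        [[0.5, 0.5, 0], [0, 0.4, 0.6], [0, 0.33, 0.67]],
    )


class TestNormalization:
    def test_row_with_printed_rounding_slack_is_rescaled(self):
        out = normalize_transition_rows([[0.19, 0.63, 0.19]] * 3)
        np.testing.assert_allclose(out[0], np.array([0.19, 0.63, 0.19]) / 1.01, rtol=1e-15)

    def test_identity_is_unchanged(self):
        np.testing.assert_array_equal(normalize_transition_rows(np.eye(3)), np.eye(3))

    def test_already_stochastic_row_is_unchanged(self):
        row = [[0.0, 0.05, 0.95]] * 3
        np.testing.assert_allclose(normalize_transition_rows(row)[0], row[0], rtol=1e-15)

    def test_zero_entries_stay_zero_and_order_is_preserved(self, rng):
        m = rng.uniform(0, 2, size=(3, 3))
        m[0, 1] = 0.0
        out = normalize_transition_rows(m)
        assert out[0, 1] == 0.0
        for i in range(3):
            assert list(np.argsort(out[i])) == list(np.argsort(m[i]))

    def test_all_zero_row_is_invalid(self):
        with pytest.raises(ValueError, match="row 1"):
            normalize_transition_rows([[1, 0, 0], [0, 0, 0], [0, 0, 1]])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            normalize_transition_rows([[-0.1, 0.6, 0.5]] * 3)


class TestRunCohort:
    def test_vi_tdcs_three_month_occupancy_matches_published_split(self):
        trace = run_cohort(ModelSpec(), vi_transition_model())
        np.testing.assert_array_equal(
            np.round(trace.final * 100).astype(int), [28, 57, 15]
        )

    def test_tdcs_three_month_occupancy_matches_published_split(self):
        trace = run_cohort(ModelSpec(), tdcs_transition_model())
        np.testing.assert_array_equal(
            np.round(trace.final * 100).astype(int), [0, 36, 64]
        )

    def test_identity_matrices_leave_occupancy_fixed(self):
        trace = run_cohort(ModelSpec(), TransitionModel(np.eye(3), np.eye(3)))
        np.testing.assert_array_equal(trace.occupancy, np.tile([0, 0, 1.0], (7, 1)))

    def test_trace_length_and_probability_conservation(self, rng):
        for _ in range(20):
            tm = TransitionModel(
                random_transition_matrix(rng), random_transition_matrix(rng, zeros=True)
            )
            spec = ModelSpec(n_transitions=int(rng.integers(1, 12)))
            trace = run_cohort(spec, tm)
            assert len(trace) == spec.n_transitions + 1
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_agrees_with_stepwise_oracle_on_random_matrices(self, rng):
        """Oracle: explicit per-state loops, no matrix algebra."""
        for _ in range(200):
            ind = random_transition_matrix(rng)
            mnt = random_transition_matrix(rng, zeros=True)
            spec = ModelSpec(n_transitions=6)
            trace = run_cohort(spec, TransitionModel(ind, mnt))
            occ = [list(spec.initial_occupancy)]
            for k in range(6):
                m = ind if k == 0 else mnt
                prev = occ[-1]
                occ.append(
                    [sum(prev[i] * m[i][j] for i in range(3)) for j in range(3)]
                )
            np.testing.assert_allclose(trace.occupancy, occ, atol=1e-12)


class TestQalys:
    def test_vi_tdcs_base_case_lands_in_published_interval(self):
        trace = run_cohort(ModelSpec(), vi_transition_model())
        q = accumulate_qalys(trace, BASE_UTILITIES, ModelSpec())
        assert 0.162 <= q <= 0.164

    def test_utility_ceiling_gives_seven_full_cycles(self):
        trace = run_cohort(ModelSpec(), vi_transition_model())
        q = accumulate_qalys(trace, UtilitySet([1, 1, 1], [0, 0, 0]), ModelSpec())
        assert q == pytest.approx(7 * CYC, rel=1e-12)

    def test_absorbing_severe_state_closed_form(self):
        trace = run_cohort(ModelSpec(), TransitionModel.absorbing("severe"))
        q = accumulate_qalys(trace, BASE_UTILITIES, ModelSpec())
        assert q == pytest.approx(7 * 0.44 * CYC, rel=1e-12)
        assert 0.116 <= q <= 0.119  # published standard-care interval

    def test_exclude_initial_state_drops_one_cycle(self):
        spec = ModelSpec(counting=EXCLUDE_INITIAL)
        trace = run_cohort(spec, TransitionModel.absorbing("severe"))
        q = accumulate_qalys(trace, BASE_UTILITIES, spec)
        assert q == pytest.approx(6 * 0.44 * CYC, rel=1e-12)

    @given(st.floats(0.44, 1.0))
    def test_qaly_monotone_in_state_utility_and_bounded(self, u_mild):
        spec = ModelSpec()
        trace = run_cohort(spec, vi_transition_model())
        lo = accumulate_qalys(trace, UtilitySet([0.77, 0.63, 0.44], [0] * 3), spec)
        hi = accumulate_qalys(trace, UtilitySet([max(u_mild, 0.77), 0.63, 0.44], [0] * 3), spec)
        assert hi >= lo
        assert hi <= 7 * CYC

    def test_identity_chain_accrues_initial_state_utility_only(self):
        spec = ModelSpec()
        trace = run_cohort(spec, TransitionModel(np.eye(3), np.eye(3)))
        q = accumulate_qalys(trace, BASE_UTILITIES, spec)
        assert q == pytest.approx(7 * CYC * 0.44, rel=1e-12)


class TestCosts:
    def test_zero_state_costs_leave_intervention_only(self):
        trace = run_cohort(ModelSpec(), vi_transition_model())
        assert accumulate_costs(trace, [0, 0, 0], 2736.64, ModelSpec()) == 2736.64

    def test_absorbing_severe_accrues_seven_severe_cycles(self):
        trace = run_cohort(ModelSpec(), TransitionModel.absorbing("severe"))
        assert accumulate_costs(trace, [10.0, 20.0, 30.0], 0.0, ModelSpec()) == pytest.approx(
            7 * 30.0, rel=1e-12
        )

    def test_uniform_state_cost_is_transition_invariant(self, rng):
        spec = ModelSpec()
        for _ in range(10):
            tm = TransitionModel(
                random_transition_matrix(rng), random_transition_matrix(rng)
            )
            total = accumulate_costs(run_cohort(spec, tm), [55.0] * 3, 100.0, spec)
            assert total == pytest.approx(100.0 + 7 * 55.0, rel=1e-12)

    def test_negative_costs_rejected(self):
        trace = run_cohort(ModelSpec(), vi_transition_model())
        with pytest.raises(ValueError):
            accumulate_costs(trace, [-1.0, 0, 0], 0.0, ModelSpec())
        with pytest.raises(ValueError):
            accumulate_costs(trace, [0, 0, 0], -5.0, ModelSpec())


def test_trace_export_one_row_per_cycle():
    trace = run_cohort(ModelSpec(), vi_transition_model())
    df = trace.to_frame()
    assert list(df.columns) == ["cycle", "mild", "moderate", "severe"]
    assert len(df) == 7 and list(df["cycle"]) == list(range(7))
    np.testing.assert_allclose(df[["mild", "moderate", "severe"]].sum(axis=1), 1.0)


class TestTypes:
    def test_health_states_cover_nrs_scale(self):
        assert HealthState("mild", (0, 3)).index == 0
        with pytest.raises(ValueError):
            HealthState("mild", (0, 4))
        with pytest.raises(ValueError):
            HealthState("agonizing", (0, 3))

    def test_transition_model_requires_stochastic_rows(self):
        with pytest.raises(ValueError):
            TransitionModel(np.full((3, 3), 0.5), np.eye(3))

    def test_trace_rejects_non_probability_vectors(self):
        with pytest.raises(ValueError):
            CohortTrace(np.array([[0.5, 0.2, 0.2]]))

    def test_utilities_must_decrease_with_severity(self):
        with pytest.raises(ValueError):
            UtilitySet([0.4, 0.6, 0.8], [0.1] * 3)

    def test_spec_validates_initial_occupancy(self):
        with pytest.raises(ValueError):
            ModelSpec(initial_occupancy=[0.5, 0.2, 0.2])
        with pytest.raises(ValueError):
            ModelSpec(n_transitions=0)
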