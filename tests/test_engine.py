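"""Transition-matrix assembly and cohort propagation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fitcea import (
    ACTIVITY_STATES,
    DISEASE_STATES,
    STATE_ORDER,
    DistributionSpec,
    HealthState,
    ModelSpecificationError,
    build_transition_matrix,
    microsimulate,
    run_cohort,
)
from fitcea.engine import assemble_matrix
from conftest import zero_epidemiology

DEAD = 8


class TestMatrixAssembly:
    def test_inactive_row_hand_derived(self, base_params):
        # independent hand arithmetic over the published EuroFIT inactive row:
        # moves at their beta means, conditioned on the disease/death mass
        to_moderate = 0.34 / (0.34 + 5.7)
        to_recommended = 59.4 / (59.4 + 19.6)
        disease_death = (0.015 + 0.011 + 0.005 + 0.0046 + 0.010) + 0.016
        assert disease_death == pytest.approx(0.0616)
        stay = (1.0 - disease_death) - to_moderate - to_recommended
        tm = build_transition_matrix(base_params, "eurofit")
        assert tm.entries[0, 0] == pytest.approx(stay, abs=1e-12)
        assert tm.entries[0, 1] == pytest.approx(to_moderate, abs=1e-12)
        assert tm.entries[0, 2] == pytest.approx(to_recommended, abs=1e-12)
        assert tm.entries[0, DEAD] == 0.016
        assert tm.move_rescale[0] == 1.0

    def test_moderate_row_needs_rescale(self, base_params):
        # EuroFIT moderately-active moves sum to 0.9547 > available 0.9515:
        # the guard rescales them proportionally and the stay mass is zero
        tm = build_transition_matrix(base_params, "eurofit")
        available = 1.0 - (0.011 + 0.009 + 0.0038 + 0.0033 + 0.0094) - 0.012
        moves = 0.44 / 5.0 + 33.8 / 39.0
        assert moves > available
        assert tm.move_rescale[1] == pytest.approx(available / moves)
        assert tm.entries[1, 1] == pytest.approx(0.0, abs=1e-12)
        assert tm.entries[1, 0] / tm.entries[1, 2] == pytest.approx(
            (0.44 / 5.0) / (33.8 / 39.0), rel=1e-12)

    def test_stroke_row(self, base_params):
        for arm in ("eurofit", "control"):
            tm = build_transition_matrix(base_params, arm)
            stroke = STATE_ORDER.index(HealthState.STROKE)
            assert tm.entries[stroke, stroke] == pytest.approx(0.600)
            assert tm.entries[stroke, DEAD] == pytest.approx(0.400)
            assert tm.entries[stroke].sum() == pytest.approx(1.0, abs=1e-15)

    def test_row_stochastic_and_structure(self, base_params):
        for arm in ("eurofit", "control"):
            m = build_transition_matrix(base_params, arm).entries
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all() and (m <= 1).all()
            # death is absorbing
            np.testing.assert_array_equal(m[DEAD], np.eye(9)[DEAD])
            # disease rows: mass only on themselves and death
            for d in range(3, 8):
                off = np.delete(m[d], [d, DEAD])
                assert (off == 0).all()
            # disease states entered only from activity states
            assert (m[3:8, :3] == 0).all()

    def test_no_conditioning_when_row_already_stochastic(self, base_params):
        params = zero_epidemiology(base_params)
        block = params.activity_transitions["control"]
        means = block.matrix(kind="mean")
        tm = build_transition_matrix(params, "control")
        # off-diagonal moves pass through untouched; stay absorbs the residual
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert tm.entries[i, j] == means[i, j]
        np.testing.assert_allclose(tm.entries[:3, :3].sum(axis=1), 1.0, atol=1e-12)
        assert (tm.entries[:3, 3:] == 0).all()

    def test_excess_disease_mass_rejected(self, base_params):
        epi = base_params.epidemiology
        sick = dataclasses.replace(
            epi, activity_mortality={k: 0.999 for k in epi.activity_mortality})
        params = dataclasses.replace(base_params, epidemiology=sick)
        with pytest.raises(ModelSpecificationError):
            build_transition_matrix(params, "control")

    def test_invalid_cycle_and_arm(self, base_params):
        with pytest.raises(ModelSpecificationError):
            build_transition_matrix(base_params, "placebo")
        with pytest.raises(ModelSpecificationError):
            build_transition_matrix(base_params, "eurofit", cycle_index=0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        moves=st.lists(st.floats(0.0, 1.0), min_size=6, max_size=6),
        incidence=st.lists(st.floats(0.0, 0.05), min_size=15, max_size=15),
        mortality=st.lists(st.floats(0.0, 0.05), min_size=8, max_size=8),
    )
    def test_assembled_matrix_always_row_stochastic(self, moves, incidence, mortality):
        m = np.zeros((3, 3))
        m[~np.eye(3, dtype=bool)] = moves
        entries, _ = assemble_matrix(
            m, np.array(incidence).reshape(3, 5), np.array(mortality[:3]),
            np.array(mortality[3:]))
        np.testing.assert_allclose(entries.sum(axis=1), 1.0, atol=1e-12)
        assert (entries >= 0).all() and (entries <= 1).all()


class TestCohortTrace:
    def test_mass_conservation_and_shape(self, base_params):
        for arm in ("eurofit", "control"):
            trace = run_cohort(base_params, arm)
            assert trace.occupancy.shape == (6, 9)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 10_000, atol=1e-6)
            assert (trace.occupancy >= 0).all()
            assert (np.diff(trace.occupancy[:, DEAD]) >= -1e-12).all()

    def test_initial_row_is_activity_only(self, base_params):
        trace = run_cohort(base_params, "eurofit")
        np.testing.assert_allclose(trace.occupancy[0, :3], [1750, 1050, 7200])
        assert (trace.occupancy[0, 3:] == 0).all()

    def test_no_exit_paths_no_deaths(self, base_params):
        trace = run_cohort(zero_epidemiology(base_params), "eurofit")
        assert (trace.occupancy[:, DEAD] == 0).all()
        assert (trace.occupancy[:, 3:8] == 0).all()

    def test_effect_duration_switches_matrix(self, base_params):
        params = base_params.with_overrides(effect_duration_years=1)
        control = build_transition_matrix(params, "control").entries
        year1 = build_transition_matrix(params, "eurofit", cycle_index=1).entries
        year2 = build_transition_matrix(params, "eurofit", cycle_index=2).entries
        assert not np.array_equal(year1, control)
        np.testing.assert_array_equal(year2, control)

    def test_stationary_when_effect_spans_horizon(self, base_params):
        mats = [build_transition_matrix(base_params, "eurofit", cycle_index=t).entries
                for t in range(1, 6)]
        for m in mats[1:]:
            np.testing.assert_array_equal(m, mats[0])

    @pytest.mark.parametrize("disease", DISEASE_STATES)
    def test_mortality_monotonicity(self, base_params, disease):
        """Raising one disease mortality never lowers final-cycle deaths."""
        final_dead = run_cohort(base_params, "control").occupancy[-1, DEAD]
        epi = base_params.epidemiology
        raised = dict(epi.disease_mortality)
        raised[disease] = min(raised[disease] + 0.2, 1.0)
        params = dataclasses.replace(
            base_params, epidemiology=dataclasses.replace(epi, disease_mortality=raised))
        assert run_cohort(params, "control").occupancy[-1, DEAD] >= final_dead


class TestMicrosimulationOracle:
    def test_cohort_matches_microsimulation(self, base_params):
        """Expected occupancy equals an individual-level simulation within
        three standard errors of its multinomial sampling noise."""
        n = 1_000_000
        cohort = run_cohort(base_params, "eurofit")
        micro = microsimulate(base_params, "eurofit", n_individuals=n, seed=2020)
        p = cohort.occupancy / 10_000.0
        se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n)
        diff = np.abs(micro.occupancy / n - p)
        assert (diff <= 3 * se + 1e-9).all()
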