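"""Synthetic trial generation and transition estimation."""

import numpy as np
import pandas as pd
import pytest

from fitcea import (
    EstimationError,
    HealthState,
    SyntheticTrial,
    estimate_transitions,
    generate_trial,
    parameters_from_trial,
    reference_generating_matrices,
    run_deterministic,
    run_psa,
)

INIT = np.array([0.175, 0.105, 0.720])
IDENTITY = {"eurofit": np.eye(3), "control": np.eye(3)}


def _trial_from_counts(counts: dict[str, np.ndarray], seed=0) -> SyntheticTrial:
    """Build a trial table with exact per-cell transition counts."""
    cats = ["inactive", "moderate", "recommended"]
    records = []
    pid = 0
    for arm, matrix in counts.items():
        for i, b in enumerate(cats):
            for j, m in enumerate(cats):
                for _ in range(int(matrix[i, j])):
                    records.append({"participant": pid, "arm": arm,
                                    "baseline": b, "month12": m})
                    pid += 1
    data = pd.DataFrame(records)
    return SyntheticTrial(data=data, n_per_arm={a: len(d) for a, d in counts.items()},
                          true_transitions={}, seed=seed)


class TestGenerateTrial:
    def test_identity_transitions_keep_categories(self):
        trial = generate_trial(200, IDENTITY, INIT, seed=4)
        assert (trial.data["baseline"] == trial.data["month12"]).all()

    def test_seed_reproducibility(self):
        a = generate_trial(100, IDENTITY, INIT, seed=4)
        b = generate_trial(100, IDENTITY, INIT, seed=4)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_baseline_frequencies_multinomial(self):
        """n = 560 and the trial's baseline split: expect about 98/59/403."""
        trial = generate_trial(560, IDENTITY, INIT, seed=4)
        counts = trial.arm_table("eurofit")["baseline"].value_counts()
        expected = 560 * INIT
        se = np.sqrt(560 * INIT * (1 - INIT))
        for cat, mean, sd in zip(["inactive", "moderate", "recommended"], expected, se):
            assert abs(counts.get(cat, 0) - mean) <= 3 * sd

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_trial(100, {"eurofit": np.full((3, 3), 0.5)}, INIT, seed=1)
        with pytest.raises(ValueError):
            generate_trial(0, IDENTITY, INIT, seed=1)
        with pytest.raises(ValueError):
            generate_trial(10, IDENTITY, np.array([0.5, 0.2, 0.2]), seed=1)

    def test_csv_round_trip(self, tmp_path):
        trial = generate_trial(50, IDENTITY, INIT, seed=4)
        path = tmp_path / "trial.csv"
        trial.to_csv(path)
        reloaded = SyntheticTrial.from_csv(path)
        pd.testing.assert_frame_equal(reloaded.data, trial.data)


class TestEstimateTransitions:
    def test_observed_fractions_and_conjugate_counts(self):
        counts = {"eurofit": np.array([[18, 5, 77], [10, 10, 80], [5, 5, 90]])}
        trial = _trial_from_counts(counts)
        points, specs, degenerate = estimate_transitions(trial, "eurofit")
        np.testing.assert_allclose(points[0], [0.18, 0.05, 0.77])
        np.testing.assert_allclose(points.sum(axis=1), 1.0)
        spec = specs[(HealthState.INACTIVE, HealthState.INACTIVE)]
        assert (spec.param1, spec.param2) == (18, 82)
        spec = specs[(HealthState.INACTIVE, HealthState.RECOMMENDED)]
        assert (spec.param1, spec.param2) == (77, 23)
        assert degenerate == []

    def test_degenerate_cell_flagged(self):
        counts = {"eurofit": np.array([[100, 0, 0], [0, 50, 0], [0, 0, 50]])}
        trial = _trial_from_counts(counts)
        points, specs, degenerate = estimate_transitions(trial, "eurofit")
        assert points[0, 0] == 1.0
        assert specs[(HealthState.INACTIVE, HealthState.INACTIVE)].is_fixed
        assert (HealthState.INACTIVE, HealthState.INACTIVE) in degenerate

    def test_empty_baseline_row_rejected(self):
        counts = {"eurofit": np.array([[10, 0, 0], [0, 0, 0], [0, 0, 10]])}
        trial = _trial_from_counts(counts)
        with pytest.raises(EstimationError, match="moderate"):
            estimate_transitions(trial, "eurofit")

    def test_missing_arm_rejected(self):
        trial = _trial_from_counts({"eurofit": np.full((3, 3), 5)})
        with pytest.raises(EstimationError, match="control"):
            estimate_transitions(trial, "control")


class TestParameterRecovery:
    def test_recovery_within_binomial_error(self, base_params):
        """Estimates at n = 20,000 sit within 3 binomial SEs of the truth."""
        truth = reference_generating_matrices(base_params)
        trial = generate_trial(20_000, {"control": truth["control"],
                                        "eurofit": truth["eurofit"]}, INIT, seed=12)
        for arm in ("eurofit", "control"):
            points, _, _ = estimate_transitions(trial, arm)
            table = trial.arm_table(arm)
            for i, cat in enumerate(["inactive", "moderate", "recommended"]):
                n_row = (table["baseline"] == cat).sum()
                p = truth[arm][i]
                se = np.sqrt(p * (1 - p) / n_row)
                assert (np.abs(points[i] - p) <= 3 * se + 1e-12).all()

    def test_estimation_error_shrinks_with_n(self, base_params):
        truth = reference_generating_matrices(base_params)
        errors = {}
        for n in (500, 20_000):
            trial = generate_trial(n, truth, INIT, seed=12)
            err = 0.0
            for arm in ("eurofit", "control"):
                points, _, _ = estimate_transitions(trial, arm)
                err += np.abs(points - truth[arm]).sum()
            errors[n] = err
        assert errors[20_000] < errors[500]

    def test_end_to_end_pipeline_and_convergence(self, base_params):
        """A parameter set estimated from synthetic data runs the full
        deterministic + PSA pipeline, and its increments approach the ones
        computed from the generating matrices as the trial grows."""
        import dataclasses

        from fitcea import ARMS, ActivityTransitionBlock, DistributionSpec
        from fitcea.states import ACTIVITY_STATES

        truth = reference_generating_matrices(base_params)
        truth_blocks = {
            arm: ActivityTransitionBlock(arm=arm, probs={
                (s, t): DistributionSpec.fixed(truth[arm][i, j])
                for i, s in enumerate(ACTIVITY_STATES)
                for j, t in enumerate(ACTIVITY_STATES)})
            for arm in ARMS}
        reference = run_deterministic(
            dataclasses.replace(base_params, activity_transitions=truth_blocks))
        errs = {}
        for n in (500, 20_000):
            trial = generate_trial(n, truth, INIT, seed=12)
            params = parameters_from_trial(trial, base_params)
            result = run_deterministic(params)
            run_psa(params, n_sims=5, seed=3)  # pipeline must accept estimates
            errs[n] = abs(result.incremental_qalys - reference.incremental_qalys)
        assert errs[20_000] < errs[500]
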