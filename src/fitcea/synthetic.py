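"""Synthetic trial data for the activity-transition estimation path.

The model's arm-specific activity transitions are estimated from a
randomised trial as the fraction of participants in each baseline activity
category observed in each category at 12 months. This module generates
individual-level data with exactly that structure (baseline category drawn
from the population activity distribution, 12-month category from a known
per-arm transition matrix) and re-estimates transition probabilities and
their beta distributions from it, so the estimation path can be exercised
and validated without access to the original trial dataset.

Beta distributions use conjugate counts: alpha = number of participants
making the transition, beta = remainder of the baseline row. Rows of point
estimates therefore sum to one exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import ActivityTransitionBlock, DistributionSpec, ModelParameters
from .states import ACTIVITY_STATES, ARMS

_CATEGORIES = [s.value for s in ACTIVITY_STATES]


class EstimationError(ValueError):
    """The trial data cannot support the requested estimate."""


@dataclasses.dataclass(frozen=True)
class SyntheticTrial:
    """Per-participant baseline and 12-month activity categories.

    ``data`` has columns participant, arm, baseline, month12;
    ``true_transitions`` holds the generating 3x3 row-stochastic matrix per
    arm for parameter-recovery checks.
    """

    data: pd.DataFrame
    n_per_arm: Mapping[str, int]
    true_transitions: Mapping[str, np.ndarray]
    seed: int

    def arm_table(self, arm: str) -> pd.DataFrame:
        return self.data[self.data["arm"] == arm]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, seed: int = -1) -> "SyntheticTrial":
        data = pd.read_csv(path)
        n = {arm: int((data["arm"] == arm).sum()) for arm in data["arm"].unique()}
        return cls(data=data, n_per_arm=n, true_transitions={}, seed=seed)


def generate_trial(
    n_per_arm: int | Mapping[str, int],
    true_transitions: Mapping[str, np.ndarray],
    initial_dist: np.ndarray,
    seed: int,
) -> SyntheticTrial:
    """Simulate per-arm 12-month activity-category transitions.

    Baseline categories are multinomial draws from ``initial_dist``;
    each participant's 12-month category is drawn from the row of the arm's
    ``true_transitions`` matrix (rows must sum to 1).
    """
    if isinstance(n_per_arm, int):
        n_per_arm = {arm: n_per_arm for arm in true_transitions}
    initial_dist = np.asarray(initial_dist, dtype=float)
    if initial_dist.shape != (3,) or abs(initial_dist.sum() - 1.0) > 1e-9:
        raise ValueError("initial_dist must be 3 proportions summing to 1")
    rng = np.random.default_rng(seed)
    records = []
    pid = 0
    for arm, matrix in true_transitions.items():
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (3, 3) or not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"true_transitions[{arm!r}] rows must sum to 1")
        n = n_per_arm[arm]
        if n < 1:
            raise ValueError(f"n_per_arm[{arm!r}] must be >= 1")
        baseline = rng.choice(3, size=n, p=initial_dist)
        for b in baseline:
            m12 = rng.choice(3, p=matrix[b])
            records.append({
                "participant": pid, "arm": arm,
                "baseline": _CATEGORIES[b], "month12": _CATEGORIES[m12],
            })
            pid += 1
    return SyntheticTrial(
        data=pd.DataFrame(records),
        n_per_arm=dict(n_per_arm),
        true_transitions={a: np.asarray(m, dtype=float) for a, m in true_transitions.items()},
        seed=seed,
    )


def estimate_transitions(
    trial: SyntheticTrial, arm: str
) -> tuple[np.ndarray, dict, list]:
    """Row-wise observed transition fractions and conjugate beta specs.

    Returns ``(point_matrix, specs, degenerate_cells)`` where
    ``specs[(from, to)]`` is a beta spec with alpha = transition count and
    beta = row total minus count. Cells whose count or complement is zero
    cannot carry a proper beta; they are returned as fixed specs and listed
    in ``degenerate_cells``.
    """
    table = trial.arm_table(arm)
    if table.empty:
        raise EstimationError(f"no participants in arm {arm!r}")
    counts = np.zeros((3, 3))
    for i, b in enumerate(_CATEGORIES):
        for j, m in enumerate(_CATEGORIES):
            counts[i, j] = ((table["baseline"] == b) & (table["month12"] == m)).sum()
    row_totals = counts.sum(axis=1)
    empty = [_CATEGORIES[i] for i in range(3) if row_totals[i] == 0]
    if empty:
        raise EstimationError(f"arm {arm!r}: empty baseline rows {empty}")
    points = counts / row_totals[:, None]
    specs: dict = {}
    degenerate: list = []
    for i, s in enumerate(ACTIVITY_STATES):
        for j, t in enumerate(ACTIVITY_STATES):
            a, b = counts[i, j], row_totals[i] - counts[i, j]
            if a > 0 and b > 0:
                specs[(s, t)] = DistributionSpec.beta(a, b, points[i, j])
            else:
                specs[(s, t)] = DistributionSpec.fixed(points[i, j])
                degenerate.append((s, t))
    return points, specs, degenerate


def transitions_from_trial(trial: SyntheticTrial, arm: str) -> ActivityTransitionBlock:
    """Estimated transitions packaged as an engine-ready block."""
    _, specs, _ = estimate_transitions(trial, arm)
    return ActivityTransitionBlock(arm=arm, probs=specs)


def parameters_from_trial(trial: SyntheticTrial, base: ModelParameters) -> ModelParameters:
    """Replace both arms' activity transitions with trial estimates."""
    blocks = {arm: transitions_from_trial(trial, arm) for arm in ARMS}
    return dataclasses.replace(base, activity_transitions=blocks)


def block_to_matrix(block: ActivityTransitionBlock, kind: str = "mean") -> np.ndarray:
    """3x3 cell values of a block (thin convenience wrapper)."""
    return block.matrix(kind=kind)


def reference_generating_matrices(params: ModelParameters) -> dict[str, np.ndarray]:
    """Row-stochastic generating matrices from a parameter set's blocks.

    The blocks' distribution means are near row-stochastic; they are
    normalised exactly so they can seed :func:`generate_trial`.
    """
    out = {}
    for arm in ARMS:
        m = params.activity_transitions[arm].matrix(kind="mean")
        out[arm] = m / m.sum(axis=1, keepdims=True)
    return out
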