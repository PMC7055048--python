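"""Transition-matrix assembly and cohort propagation.

Annual 9x9 transition matrices are assembled from an
:class:`~fitcea.parameters.ModelParameters` set. Activity rows combine three
ingredients: the arm's move probabilities between activity levels, the fixed
annual probabilities of developing one of five chronic conditions, and the
fixed annual probability of death. Because a condition or death pre-empts an
activity move, the activity block of each row is conditioned on the
remaining mass: the probability of staying at the current activity level is
the residual of the available mass after the moves, and if sampled or
estimated moves exceed the available mass they are rescaled proportionally
into it. Disease states are absorbing apart from death (one condition at a
time, no recovery); death is absorbing.

The deterministic analysis evaluates each activity transition at the mean
of its trial-derived beta distribution. The published beta parameters encode
the observed arm fractions (their means are near row-stochastic), whereas
the rounded probability column does not form consistent row distributions;
the rounded values remain available via ``kind="point"`` for audit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .parameters import ModelParameters
from .states import ACTIVITY_STATES, ARMS, N_STATES, STATE_ORDER

_DEAD = N_STATES - 1


class ModelSpecificationError(ValueError):
    """The parameter set cannot produce a valid transition matrix."""


@dataclasses.dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic annual transition matrix for one arm.

    ``move_rescale`` records, per activity row, the factor applied to the
    move probabilities when they exceeded the available (disease- and
    death-free) mass; 1.0 means the row needed no rescaling.
    """

    arm: str
    entries: np.ndarray
    move_rescale: np.ndarray

    def __post_init__(self):
        rowsums = self.entries.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-12):
            raise ModelSpecificationError(f"rows sum to {rowsums}, not 1")
        if (self.entries < 0).any() or (self.entries > 1).any():
            raise ModelSpecificationError("transition probabilities outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy of a closed cohort.

    ``occupancy[t]`` is the expected number of persons in each state at the
    end of cycle t (row 0 is the initial distribution).
    """

    arm: str
    cohort_size: float
    occupancy: np.ndarray  # (horizon+1, 9)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.value for s in STATE_ORDER])
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def assemble_matrix(
    moves: np.ndarray,
    incidence: np.ndarray,
    activity_mortality: np.ndarray,
    disease_mortality: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the 9x9 annual matrix from raw probability inputs.

    ``moves`` is a 3x3 array of activity-transition values whose
    off-diagonal entries are the per-cycle move probabilities (the diagonal
    is ignored and recomputed as the residual of the available mass).
    Returns ``(matrix, move_rescale)``.
    """
    available = 1.0 - incidence.sum(axis=1) - activity_mortality
    if (available <= 0).any():
        bad = [str(s) for s, a in zip(ACTIVITY_STATES, available) if a <= 0]
        raise ModelSpecificationError(
            f"disease + death mass >= 1 leaves no activity mass for rows {bad}")

    M = np.zeros((N_STATES, N_STATES))
    rescale = np.ones(3)
    for i in range(3):
        row_moves = moves[i].astype(float).copy()
        row_moves[i] = 0.0
        total = row_moves.sum()
        if total > available[i]:
            rescale[i] = available[i] / total
            row_moves *= rescale[i]
        M[i, :3] = row_moves
        # max() guards the residual against negative-zero rounding after rescale
        M[i, i] = max(available[i] - row_moves.sum(), 0.0)
        M[i, 3:8] = incidence[i]
        M[i, _DEAD] = activity_mortality[i]
    for d in range(5):
        M[3 + d, 3 + d] = 1.0 - disease_mortality[d]
        M[3 + d, _DEAD] = disease_mortality[d]
    M[_DEAD, _DEAD] = 1.0
    return M, rescale


def _arm_for_cycle(params: ModelParameters, arm: str, cycle_index: int) -> str:
    if arm == "eurofit" and cycle_index > params.effect_duration():
        return "control"
    return arm


def build_transition_matrix(
    params: ModelParameters,
    arm: str,
    cycle_index: int = 1,
    moves: np.ndarray | None = None,
) -> TransitionMatrix:
    """Annual transition matrix for ``arm`` at one-based ``cycle_index``.

    After the intervention effect has lapsed (``cycle_index`` beyond
    ``effect_duration_years``) the intervention arm reuses the control arm's
    activity transitions; occupancy never jumps, only the matrix changes.
    ``moves`` overrides the activity-transition values (used by the PSA with
    sampled cells); by default the arm block's distribution means are used.
    """
    if arm not in ARMS:
        raise ModelSpecificationError(f"unknown arm {arm!r}")
    if cycle_index < 1:
        raise ModelSpecificationError(f"cycle_index must be >= 1, got {cycle_index}")
    effective = _arm_for_cycle(params, arm, cycle_index)
    if moves is None:
        moves = params.activity_transitions[effective].matrix(kind="mean")
    epi = params.epidemiology
    entries, rescale = assemble_matrix(
        moves, epi.incidence_matrix(), epi.activity_mortality_vector(),
        epi.disease_mortality_vector())
    return TransitionMatrix(arm=arm, entries=entries, move_rescale=rescale)


def run_cohort(params: ModelParameters, arm: str) -> CohortTrace:
    """Propagate the cohort over the model horizon (expected occupancy)."""
    horizon = params.horizon_years
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0] = params.cohort_size * params.initial_vector()
    for t in range(1, horizon + 1):
        tm = build_transition_matrix(params, arm, cycle_index=t)
        occ[t] = occ[t - 1] @ tm.entries
    return CohortTrace(arm=arm, cohort_size=float(params.cohort_size), occupancy=occ)


def microsimulate(
    params: ModelParameters, arm: str, n_individuals: int, seed: int
) -> CohortTrace:
    """Individual-level simulation with the same matrices as the cohort run.

    Propagates ``n_individuals`` through the state space by multinomial
    sampling; the expected occupancy equals the cohort trace (scaled to
    ``n_individuals``), which makes this an independent stochastic check of
    the deterministic propagation.
    """
    rng = np.random.default_rng(seed)
    horizon = params.horizon_years
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0] = rng.multinomial(n_individuals, params.initial_vector())
    for t in range(1, horizon + 1):
        tm = build_transition_matrix(params, arm, cycle_index=t)
        counts = np.zeros(N_STATES)
        for s in range(N_STATES):
            n_here = int(occ[t - 1, s])
            if n_here:
                counts += rng.multinomial(n_here, tm.entries[s])
        occ[t] = counts
    return CohortTrace(arm=arm, cohort_size=float(n_individuals), occupancy=occ)
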