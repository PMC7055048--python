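"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte Carlo simulation: each draw
samples every trial-derived (non-fixed) parameter from its stated
distribution -- beta for activity-transition move probabilities (sampled
independently per arm), beta for activity-state utilities and gamma for
activity-state costs (sampled once per draw and shared by both arms, since
they describe the same states) -- rebuilds the transition matrices with the
same residual-stay kernel as the deterministic engine, reruns both arms and
records the incremental cost and QALY pair.

Reproducibility: one root seed; draw i uses the i-th spawned child of
``numpy.random.SeedSequence(seed)``, so enlarging ``n_sims`` extends the
draw sequence without reshuffling earlier draws.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .engine import assemble_matrix
from .parameters import DistributionSpec, ModelParameters
from .states import ACTIVITY_STATES

#: Default willingness-to-pay grid (EUR/QALY): 0 to 50,000 in steps of 1,000,
#: covering the commonly quoted 10,000 / 22,000 / 34,000 thresholds.
DEFAULT_WTP_GRID = np.arange(0, 50_001, 1_000)


class PSAError(RuntimeError):
    """A draw failed; the message carries the draw index and cause."""


@dataclasses.dataclass(frozen=True)
class PSADraws:
    """Paired incremental (cost, QALY) draws from the Monte Carlo PSA."""

    n_sims: int
    seed: int
    delta_cost: np.ndarray
    delta_qalys: np.ndarray

    def __post_init__(self):
        if len(self.delta_cost) != self.n_sims or len(self.delta_qalys) != self.n_sims:
            raise ValueError("draw arrays must have length n_sims")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "draw": np.arange(self.n_sims),
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class CEAC:
    """Cost-effectiveness acceptability curve.

    ``probability[k]`` is the fraction of draws with positive net monetary
    benefit ``thresholds[k] * dQALY - dCost`` (strict inequality).
    """

    thresholds: np.ndarray
    probability: np.ndarray

    def at(self, wtp: float) -> float:
        idx = np.nonzero(np.isclose(self.thresholds, wtp))[0]
        if len(idx) == 0:
            raise KeyError(f"threshold {wtp} not on the CEAC grid")
        return float(self.probability[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp_eur_per_qaly": self.thresholds,
                             "probability_cost_effective": self.probability})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _draw_values(params: ModelParameters, rng: np.random.Generator):
    """Sample one draw's raw values in the canonical order.

    Order: intervention-arm move cells (row-major, off-diagonal), control-arm
    move cells, activity utilities (current source), activity costs (current
    perspective). Fixed entries are not drawn. The stay (diagonal) cells are
    determined residually by the engine's kernel and are never sampled.
    """
    moves = {}
    for arm in ("eurofit", "control"):
        block = params.activity_transitions[arm]
        mat = block.matrix(kind="mean")
        for i, s in enumerate(ACTIVITY_STATES):
            for j, t in enumerate(ACTIVITY_STATES):
                if i == j:
                    continue
                spec = block.probs[(s, t)]
                mat[i, j] = spec.sample(rng) if not spec.is_fixed else spec.point
        moves[arm] = mat
    utilities = params.payoffs.utility_vector(kind="point")
    for i, s in enumerate(ACTIVITY_STATES):
        spec = params.payoffs.utility(s)
        if not spec.is_fixed:
            utilities[i] = spec.sample(rng)
    costs = params.payoffs.cost_vector(kind="point")
    for i, s in enumerate(ACTIVITY_STATES):
        spec = params.payoffs.annual_cost(s)
        if not spec.is_fixed:
            costs[i] = spec.sample(rng)
    return moves, utilities, costs


def sample_parameters(params: ModelParameters, rng: np.random.Generator) -> ModelParameters:
    """One PSA draw as a full parameter set.

    Every sampled entry is replaced by a ``fixed`` spec holding the drawn
    value; fixed entries are unchanged. Running the engine on the returned
    set reproduces the corresponding :func:`run_psa` draw exactly.
    """
    moves, utilities, costs = _draw_values(params, rng)

    new_blocks = {}
    for arm in ("eurofit", "control"):
        block = params.activity_transitions[arm]
        probs = dict(block.probs)
        for i, s in enumerate(ACTIVITY_STATES):
            for j, t in enumerate(ACTIVITY_STATES):
                if i != j and not probs[(s, t)].is_fixed:
                    probs[(s, t)] = DistributionSpec.fixed(moves[arm][i, j])
        new_blocks[arm] = dataclasses.replace(block, probs=probs)

    payoffs = params.payoffs
    source, persp = payoffs.utility_source, payoffs.perspective
    new_utils = {src: dict(payoffs.activity_utilities[src]) for src in payoffs.activity_utilities}
    new_costs = {p: dict(payoffs.activity_costs[p]) for p in payoffs.activity_costs}
    for i, s in enumerate(ACTIVITY_STATES):
        if not payoffs.activity_utilities[source][s].is_fixed:
            new_utils[source][s] = DistributionSpec.fixed(utilities[i])
        if not payoffs.activity_costs[persp][s].is_fixed:
            new_costs[persp][s] = DistributionSpec.fixed(costs[i])
    payoffs = dataclasses.replace(payoffs, activity_utilities=new_utils, activity_costs=new_costs)
    return dataclasses.replace(params, activity_transitions=new_blocks, payoffs=payoffs)


def _run_pair(params: ModelParameters, moves: dict, utilities: np.ndarray, costs: np.ndarray):
    """Both arms for one parameter draw; returns (delta_cost, delta_qalys).

    Uses the same assembly, propagation and accumulation code paths as the
    deterministic engine, so a draw whose values equal the deterministic
    analysis values reproduces the deterministic increments bit-exactly.
    """
    from .economics import accumulate_payoffs
    from .engine import CohortTrace

    epi = params.epidemiology
    inc = epi.incidence_matrix()
    act_mort = epi.activity_mortality_vector()
    dis_mort = epi.disease_mortality_vector()
    m_eurofit, _ = assemble_matrix(moves["eurofit"], inc, act_mort, dis_mort)
    m_control, _ = assemble_matrix(moves["control"], inc, act_mort, dis_mort)

    horizon = params.horizon_years
    effect = params.effect_duration()
    occ = {arm: np.empty((horizon + 1, len(utilities))) for arm in ("eurofit", "control")}
    occ["eurofit"][0] = occ["control"][0] = params.cohort_size * params.initial_vector()
    for t in range(1, horizon + 1):
        occ["eurofit"][t] = occ["eurofit"][t - 1] @ (m_eurofit if t <= effect else m_control)
        occ["control"][t] = occ["control"][t - 1] @ m_control
    totals = {
        arm: accumulate_payoffs(
            CohortTrace(arm=arm, cohort_size=float(params.cohort_size), occupancy=occ[arm]),
            params, arm, utilities=utilities, costs=costs)
        for arm in ("eurofit", "control")
    }
    return (totals["eurofit"].total_cost - totals["control"].total_cost,
            totals["eurofit"].total_qalys - totals["control"].total_qalys)


def run_psa(params: ModelParameters, n_sims: int, seed: int) -> PSADraws:
    """Monte Carlo PSA: ``n_sims`` draws, deterministic given ``seed``."""
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    children = np.random.SeedSequence(seed).spawn(n_sims)
    d_cost = np.empty(n_sims)
    d_qalys = np.empty(n_sims)
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            moves, utilities, costs = _draw_values(params, rng)
            d_cost[k], d_qalys[k] = _run_pair(params, moves, utilities, costs)
        except Exception as exc:  # no silent skipping: abort with the draw index
            raise PSAError(f"PSA draw {k} failed: {exc}") from exc
    return PSADraws(n_sims=n_sims, seed=seed, delta_cost=d_cost, delta_qalys=d_qalys)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def credibility_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Empirical central interval (linear-interpolation percentiles)."""
    draws = np.asarray(draws)
    if draws.size == 0:
        raise ValueError("no draws")
    tail = 100.0 * (1.0 - level) / 2.0
    lower, upper = np.percentile(draws, [tail, 100.0 - tail], method="linear")
    return float(lower), float(upper)


def compute_ceac(draws: PSADraws, thresholds: np.ndarray | None = None) -> CEAC:
    """Fraction of draws with positive net monetary benefit per threshold."""
    if thresholds is None:
        thresholds = DEFAULT_WTP_GRID
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds < 0).any():
        raise ValueError("willingness-to-pay thresholds must be >= 0")
    nmb = thresholds[:, None] * draws.delta_qalys[None, :] - draws.delta_cost[None, :]
    return CEAC(thresholds=thresholds, probability=(nmb > 0).mean(axis=1))
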