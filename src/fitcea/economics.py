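"""Discounted costs, QALYs and incremental cost-effectiveness measures.

QALYs multiply the time spent in each state by that state's utility; costs
multiply it by the state's annual cost. Person-years in a state during cycle
t are taken as the occupancy at the end of the cycle, and payoffs of cycle t
are discounted by (1 + r)^-(t-1): the first model year accrues undiscounted,
consistent with the published cohort totals. The one-off program cost is
incurred per intervention participant at enrollment (time zero,
undiscounted).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .engine import CohortTrace
from .parameters import ModelParameters


def discount_factor(cycle: int | np.ndarray, rate: float) -> float | np.ndarray:
    """(1 + rate)^-cycle; rate is annual, cycle in years."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return (1.0 + rate) ** (-np.asarray(cycle, dtype=float))


@dataclasses.dataclass(frozen=True)
class ArmResult:
    """Discounted cohort totals for one arm."""

    arm: str
    total_cost: float
    total_qalys: float


@dataclasses.dataclass(frozen=True)
class CEResult:
    """Incremental cost-effectiveness comparison of the two arms.

    ``icer`` is in EUR per QALY when both increments are positive; the
    ``verdict`` covers the remaining quadrants of the cost-effectiveness
    plane (``dominant``: cheaper and more effective; ``dominated``: costlier
    and less effective).
    """

    total_cost_eurofit: float
    total_cost_control: float
    total_qalys_eurofit: float
    total_qalys_control: float
    incremental_cost: float
    incremental_qalys: float
    icer: float | None
    verdict: str
    cohort_size: float

    @property
    def per_person_cost(self) -> float:
        return self.incremental_cost / self.cohort_size

    @property
    def per_person_qalys(self) -> float:
        return self.incremental_qalys / self.cohort_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "total_cost_eurofit": self.total_cost_eurofit,
            "total_qalys_eurofit": self.total_qalys_eurofit,
            "total_cost_control": self.total_cost_control,
            "total_qalys_control": self.total_qalys_control,
            "incremental_cost": self.incremental_cost,
            "incremental_qalys": self.incremental_qalys,
            "icer": self.icer if self.icer is not None else "",
            "verdict": self.verdict,
        }])


def accumulate_payoffs(
    trace: CohortTrace,
    params: ModelParameters,
    arm: str,
    utilities: np.ndarray | None = None,
    costs: np.ndarray | None = None,
) -> ArmResult:
    """Discounted total cost and QALYs of a cohort trace.

    ``utilities``/``costs`` override the per-state payoff vectors (used by
    the PSA with sampled values); by default the parameter set's point
    values are used.
    """
    if trace.occupancy.shape[0] != params.horizon_years + 1:
        raise ValueError(
            f"trace has {trace.occupancy.shape[0] - 1} cycles but the horizon is "
            f"{params.horizon_years} years")
    if utilities is None:
        utilities = params.payoffs.utility_vector(kind="point")
    if costs is None:
        costs = params.payoffs.cost_vector(kind="point")
    cycles = np.arange(1, params.horizon_years + 1)
    occ = trace.occupancy[1:]  # end-of-cycle occupancy, cycles 1..T
    df_effects = discount_factor(cycles - 1, params.discount_rate_effects)
    df_costs = discount_factor(cycles - 1, params.discount_rate_costs)
    total_qalys = float((occ @ utilities) @ df_effects)
    total_cost = float((occ @ costs) @ df_costs)
    if arm == "eurofit":
        total_cost += params.payoffs.program_cost * trace.cohort_size
    return ArmResult(arm=arm, total_cost=total_cost, total_qalys=total_qalys)


def compare_arms(
    result_eurofit: ArmResult, result_control: ArmResult, cohort_size: float
) -> CEResult:
    """Fill the incremental comparison, including dominance verdicts."""
    d_cost = result_eurofit.total_cost - result_control.total_cost
    d_qalys = result_eurofit.total_qalys - result_control.total_qalys
    icer: float | None
    if d_qalys == 0.0:
        icer, verdict = None, "no QALY difference"
    elif d_cost < 0 and d_qalys > 0:
        icer, verdict = d_cost / d_qalys, "dominant"
    elif d_cost > 0 and d_qalys < 0:
        icer, verdict = d_cost / d_qalys, "dominated"
    elif d_cost <= 0 and d_qalys < 0:
        # cheaper but less effective: ICER is cost saved per QALY forgone
        icer, verdict = d_cost / d_qalys, "icer_southwest"
    else:
        icer, verdict = d_cost / d_qalys, "icer"
    return CEResult(
        total_cost_eurofit=result_eurofit.total_cost,
        total_cost_control=result_control.total_cost,
        total_qalys_eurofit=result_eurofit.total_qalys,
        total_qalys_control=result_control.total_qalys,
        incremental_cost=d_cost,
        incremental_qalys=d_qalys,
        icer=icer,
        verdict=verdict,
        cohort_size=cohort_size,
    )


def run_deterministic(params: ModelParameters) -> CEResult:
    """Run both arms deterministically and compare them."""
    from .engine import run_cohort

    res = {
        arm: accumulate_payoffs(run_cohort(params, arm), params, arm)
        for arm in ("eurofit", "control")
    }
    return compare_arms(res["eurofit"], res["control"], params.cohort_size)
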