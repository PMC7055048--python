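"""Deterministic sensitivity and scenario analyses.

The canonical scenarios mirror the published analysis plan: a 10-year
horizon (intervention effect maintained throughout), the healthcare cost
perspective, literature-sourced activity utilities, a one-year intervention
effect, and discount-rate variants (0% and 5%, applied to costs only,
effects only, and both). Each scenario is a set of overrides on the base
parameter set; the base case is the empty override set.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import CEResult, run_deterministic
from .parameters import ModelParameters, ParameterError
from .psa import CEAC, PSADraws, compute_ceac, run_psa


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """A named set of parameter overrides relative to the base case."""

    name: str
    overrides: Mapping[str, object] = dataclasses.field(default_factory=dict)

    def apply(self, base: ModelParameters) -> ModelParameters:
        try:
            return base.with_overrides(**dict(self.overrides))
        except ParameterError as exc:
            raise ParameterError(f"scenario {self.name!r}: {exc}") from exc


BASE_CASE = ScenarioSpec("base", {})

CANONICAL_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("horizon_10y", {"horizon_years": 10}),
    ScenarioSpec("healthcare", {"perspective": "healthcare"}),
    ScenarioSpec("literature_utilities", {"utility_source": "literature"}),
    ScenarioSpec("effect_1y", {"effect_duration_years": 1}),
)

DISCOUNT_SCENARIOS: tuple[ScenarioSpec, ...] = tuple(
    ScenarioSpec(f"discount_{label}_{int(rate * 100)}pct", overrides)
    for rate in (0.0, 0.05)
    for label, overrides in (
        ("costs", {"discount_rate_costs": rate}),
        ("effects", {"discount_rate_effects": rate}),
        ("both", {"discount_rate_costs": rate, "discount_rate_effects": rate}),
    )
)


def get_scenario(name: str) -> ScenarioSpec:
    for spec in (BASE_CASE,) + CANONICAL_SCENARIOS + DISCOUNT_SCENARIOS:
        if spec.name == name:
            return spec
    raise KeyError(f"unknown scenario {name!r}")


def run_scenario(base: ModelParameters, spec: ScenarioSpec) -> CEResult:
    """Apply the overrides and run both arms deterministically."""
    return run_deterministic(spec.apply(base))


def run_scenario_psa(
    base: ModelParameters,
    spec: ScenarioSpec,
    n_sims: int,
    seed: int,
    thresholds: np.ndarray | None = None,
) -> tuple[PSADraws, CEAC]:
    """PSA under the overridden model; returns the draws and their CEAC."""
    draws = run_psa(spec.apply(base), n_sims=n_sims, seed=seed)
    return draws, compute_ceac(draws, thresholds)


def tornado(base: ModelParameters, specs: Sequence[ScenarioSpec]) -> pd.DataFrame:
    """ICER point estimates and percent change vs base per scenario.

    Dominant scenarios carry their signed (negative) ICER and are flagged
    rather than hidden, so the percent change stays well defined.
    """
    base_result = run_deterministic(base)
    if base_result.icer is None or not np.isfinite(base_result.icer):
        raise ValueError("base-case ICER is undefined; tornado needs a finite reference")
    rows = []
    for spec in specs:
        result = run_scenario(base, spec)
        icer = result.icer if result.icer is not None else np.nan
        rows.append({
            "scenario": spec.name,
            "icer": icer,
            "verdict": result.verdict,
            "dominant": result.verdict == "dominant",
            "pct_change_vs_base": 100.0 * (icer - base_result.icer) / base_result.icer,
        })
    return pd.DataFrame(rows)


def scenario_table(base: ModelParameters, specs: Sequence[ScenarioSpec]) -> pd.DataFrame:
    """Cost-effectiveness results across scenarios, one row per scenario."""
    frames = []
    for spec in specs:
        frame = run_scenario(base, spec).to_frame()
        frame.insert(0, "scenario", spec.name)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
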