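"""Parameter data model and the published model-input fixture.

Every quantity the model consumes is declarative: transition probabilities
between activity levels per trial arm (with the beta distributions used in
the probabilistic sensitivity analysis), annual disease incidence and
mortality probabilities, state utilities, annual per-person costs for the
societal and healthcare perspectives (EUR 2017), and the one-off program
cost. The packaged fixture transcribes the published parameter table
verbatim, including both the rounded point column and the distribution
parameters; see :mod:`fitcea.engine` for which value the deterministic
analysis uses.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .states import (
    ACTIVITY_STATES,
    ARMS,
    DISEASE_STATES,
    STATE_ORDER,
    HealthState,
)

PERSPECTIVES = ("societal", "healthcare")
UTILITY_SOURCES = ("trial", "literature")

_REFERENCE_RESOURCE = "reference_parameters.yaml"


class ParameterError(ValueError):
    """A parameter violates its invariant; the message names the parameter."""


# ---------------------------------------------------------------------------
# Distribution specification
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class DistributionSpec:
    """A model parameter: a point value plus its PSA sampling distribution.

    family
        ``beta`` (shape ``param1`` = alpha, ``param2`` = beta), ``gamma``
        (``param1`` = shape, ``param2`` = scale, EUR) or ``fixed`` (never
        perturbed in the PSA).
    point
        The reported central value on the natural scale (probability,
        utility per year, or EUR per person-year).
    """

    family: str
    point: float
    param1: float | None = None
    param2: float | None = None

    @classmethod
    def fixed(cls, point: float) -> "DistributionSpec":
        return cls(family="fixed", point=point)

    @classmethod
    def beta(cls, alpha: float, beta: float, point: float) -> "DistributionSpec":
        return cls(family="beta", point=point, param1=alpha, param2=beta)

    @classmethod
    def gamma(cls, shape: float, scale: float, point: float) -> "DistributionSpec":
        return cls(family="gamma", point=point, param1=shape, param2=scale)

    @property
    def is_fixed(self) -> bool:
        return self.family == "fixed"

    def mean(self) -> float:
        """Expected value of the sampling distribution.

        For ``fixed`` entries this is the point value itself. The fixture's
        beta/gamma means can differ slightly from the rounded point column;
        both are retained deliberately.
        """
        if self.family == "beta":
            return self.param1 / (self.param1 + self.param2)
        if self.family == "gamma":
            return self.param1 * self.param2
        return self.point

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "beta":
            return float(rng.beta(self.param1, self.param2))
        if self.family == "gamma":
            return float(rng.gamma(self.param1, self.param2))
        return self.point

    def validate(self, name: str, *, lower: float | None = None, upper: float | None = None) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ParameterError(f"{name}: unknown distribution family {self.family!r}")
        if self.family in ("beta", "gamma"):
            if self.param1 is None or self.param2 is None or self.param1 <= 0 or self.param2 <= 0:
                raise ParameterError(
                    f"{name}: {self.family} distribution requires positive parameters, "
                    f"got ({self.param1}, {self.param2})"
                )
        if self.family == "beta" and not (0.0 <= self.point <= 1.0):
            raise ParameterError(f"{name}: beta point estimate {self.point} outside [0, 1]")
        if self.family == "gamma" and self.point < 0:
            raise ParameterError(f"{name}: gamma point estimate {self.point} is negative")
        if lower is not None and self.point < lower:
            raise ParameterError(f"{name}: point estimate {self.point} below {lower}")
        if upper is not None and self.point > upper:
            raise ParameterError(f"{name}: point estimate {self.point} above {upper}")

    # -- structured-text round trip --------------------------------------
    def to_dict(self) -> dict:
        if self.family == "beta":
            return {"point": self.point, "dist": "beta", "alpha": self.param1, "beta": self.param2}
        if self.family == "gamma":
            return {"point": self.point, "dist": "gamma", "shape": self.param1, "scale": self.param2}
        return {"point": self.point, "dist": "fixed"}

    @classmethod
    def from_dict(cls, name: str, raw: Mapping) -> "DistributionSpec":
        if not isinstance(raw, Mapping) or "point" not in raw:
            raise ParameterError(f"{name}: expected a mapping with a 'point' entry, got {raw!r}")
        family = raw.get("dist", "fixed")
        keys = {"beta": {"point", "dist", "alpha", "beta"},
                "gamma": {"point", "dist", "shape", "scale"},
                "fixed": {"point", "dist"}}.get(family)
        if keys is None:
            raise ParameterError(f"{name}: unknown distribution family {family!r}")
        unknown = set(raw) - keys
        if unknown:
            raise ParameterError(f"{name}: unknown keys {sorted(unknown)}")
        if family == "beta":
            return cls.beta(float(raw["alpha"]), float(raw["beta"]), float(raw["point"]))
        if family == "gamma":
            return cls.gamma(float(raw["shape"]), float(raw["scale"]), float(raw["point"]))
        return cls.fixed(float(raw["point"]))


# ---------------------------------------------------------------------------
# Parameter blocks
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ActivityTransitionBlock:
    """12-month transition probabilities between activity levels, one arm.

    ``probs[(from_state, to_state)]`` holds the trial-derived estimate with
    its beta distribution. The rounded point column need not form consistent
    row distributions; the engine conditions rows on disease/death mass (see
    :func:`fitcea.engine.build_transition_matrix`).
    """

    arm: str
    probs: Mapping[tuple[HealthState, HealthState], DistributionSpec]

    def matrix(self, kind: str = "mean") -> np.ndarray:
        """3x3 array of cell values: ``kind`` is ``mean`` or ``point``."""
        out = np.empty((3, 3))
        for i, s in enumerate(ACTIVITY_STATES):
            for j, t in enumerate(ACTIVITY_STATES):
                spec = self.probs[(s, t)]
                out[i, j] = spec.mean() if kind == "mean" else spec.point
        return out

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise ParameterError(f"activity_transitions: unknown arm {self.arm!r}")
        for s in ACTIVITY_STATES:
            row = 0.0
            for t in ACTIVITY_STATES:
                spec = self.probs.get((s, t))
                if spec is None:
                    raise ParameterError(f"activity_transitions.{self.arm}.{s}.{t}: missing")
                spec.validate(f"activity_transitions.{self.arm}.{s}.{t}", lower=0.0, upper=1.0)
                row += spec.point
            if not (0.0 < row <= 1.05):
                raise ParameterError(
                    f"activity_transitions.{self.arm}.{s}: row of point estimates sums to "
                    f"{row:.4f}, outside (0, 1.05]"
                )


@dataclasses.dataclass(frozen=True)
class EpidemiologyBlock:
    """Annual probabilities of disease onset and death (all fixed inputs)."""

    disease_incidence: Mapping[tuple[HealthState, HealthState], float]
    activity_mortality: Mapping[HealthState, float]
    disease_mortality: Mapping[HealthState, float]

    def incidence_matrix(self) -> np.ndarray:
        """(3 activity x 5 disease) annual onset probabilities."""
        out = np.empty((3, 5))
        for i, a in enumerate(ACTIVITY_STATES):
            for j, d in enumerate(DISEASE_STATES):
                out[i, j] = self.disease_incidence[(a, d)]
        return out

    def activity_mortality_vector(self) -> np.ndarray:
        return np.array([self.activity_mortality[a] for a in ACTIVITY_STATES])

    def disease_mortality_vector(self) -> np.ndarray:
        return np.array([self.disease_mortality[d] for d in DISEASE_STATES])

    def validate(self) -> None:
        for (a, d), p in self.disease_incidence.items():
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"epidemiology.disease_incidence.{a}.{d}: {p} outside [0, 1]")
        for label, mapping in (("activity_mortality", self.activity_mortality),
                               ("disease_mortality", self.disease_mortality)):
            for s, p in mapping.items():
                if not (0.0 <= p <= 1.0):
                    raise ParameterError(f"epidemiology.{label}.{s}: {p} outside [0, 1]")
        inc = self.incidence_matrix().sum(axis=1) + self.activity_mortality_vector()
        for a, total in zip(ACTIVITY_STATES, inc):
            if total >= 1.0:
                raise ParameterError(
                    f"epidemiology: disease + death mass from {a} is {total:.4f} >= 1"
                )


@dataclasses.dataclass(frozen=True)
class PayoffBlock:
    """State utilities and annual costs, with perspective/utility selectors.

    All variants (societal and healthcare costs; trial and literature
    activity utilities) are carried together; ``perspective`` and
    ``utility_source`` select which the analysis uses, so scenario analyses
    are single-field overrides.
    """

    perspective: str
    utility_source: str
    activity_utilities: Mapping[str, Mapping[HealthState, DistributionSpec]]
    disease_utilities: Mapping[HealthState, DistributionSpec]
    activity_costs: Mapping[str, Mapping[HealthState, DistributionSpec]]
    disease_costs: Mapping[str, Mapping[HealthState, DistributionSpec]]
    program_cost: float

    def utility(self, state: HealthState) -> DistributionSpec:
        if state is HealthState.DEAD:
            return DistributionSpec.fixed(0.0)
        if state.category == "activity":
            return self.activity_utilities[self.utility_source][state]
        return self.disease_utilities[state]

    def annual_cost(self, state: HealthState) -> DistributionSpec:
        if state is HealthState.DEAD:
            return DistributionSpec.fixed(0.0)
        if state.category == "activity":
            return self.activity_costs[self.perspective][state]
        return self.disease_costs[self.perspective][state]

    def utility_vector(self, kind: str = "point") -> np.ndarray:
        return np.array([
            self.utility(s).point if kind == "point" else self.utility(s).mean()
            for s in STATE_ORDER
        ])

    def cost_vector(self, kind: str = "point") -> np.ndarray:
        return np.array([
            self.annual_cost(s).point if kind == "point" else self.annual_cost(s).mean()
            for s in STATE_ORDER
        ])

    def validate(self) -> None:
        if self.perspective not in PERSPECTIVES:
            raise ParameterError(f"payoffs.perspective: {self.perspective!r} not in {PERSPECTIVES}")
        if self.utility_source not in UTILITY_SOURCES:
            raise ParameterError(
                f"payoffs.utility_source: {self.utility_source!r} not in {UTILITY_SOURCES}"
            )
        if self.program_cost < 0:
            raise ParameterError(f"payoffs.program_cost: {self.program_cost} is negative")
        for source in UTILITY_SOURCES:
            for a in ACTIVITY_STATES:
                self.activity_utilities[source][a].validate(
                    f"payoffs.utilities.{source}.{a}", lower=0.0, upper=1.0)
        for d in DISEASE_STATES:
            self.disease_utilities[d].validate(f"payoffs.utilities.disease.{d}", lower=0.0, upper=1.0)
        for persp in PERSPECTIVES:
            for s in ACTIVITY_STATES:
                self.activity_costs[persp][s].validate(f"payoffs.costs.{persp}.{s}", lower=0.0)
            for d in DISEASE_STATES:
                self.disease_costs[persp][d].validate(f"payoffs.costs.{persp}.{d}", lower=0.0)


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """Complete, validated parameter set for one model run."""

    initial_activity: Mapping[HealthState, float]
    cohort_size: int
    horizon_years: int
    cycle_length_years: int
    discount_rate_costs: float
    discount_rate_effects: float
    activity_transitions: Mapping[str, ActivityTransitionBlock]
    epidemiology: EpidemiologyBlock
    payoffs: PayoffBlock
    effect_duration_years: int | str = "horizon"

    def effect_duration(self) -> int:
        """Number of cycles the intervention-arm transitions apply."""
        if self.effect_duration_years == "horizon":
            return self.horizon_years
        return int(self.effect_duration_years)

    def initial_vector(self) -> np.ndarray:
        out = np.zeros(len(STATE_ORDER))
        for i, s in enumerate(ACTIVITY_STATES):
            out[i] = self.initial_activity[s]
        return out

    def validate(self) -> None:
        total = sum(self.initial_activity.get(a, 0.0) for a in ACTIVITY_STATES)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"initial_activity: proportions sum to {total!r}, not 1")
        if self.cohort_size <= 0:
            raise ParameterError(f"cohort_size: {self.cohort_size} must be positive")
        if self.horizon_years < 1:
            raise ParameterError(f"horizon_years: {self.horizon_years} must be >= 1")
        if self.cycle_length_years != 1:
            raise ParameterError("cycle_length_years: only annual cycles are supported")
        for label, r in (("discount_rate_costs", self.discount_rate_costs),
                         ("discount_rate_effects", self.discount_rate_effects)):
            if not (0.0 <= r <= 1.0):
                raise ParameterError(f"{label}: {r} outside [0, 1]")
        if self.effect_duration_years != "horizon" and int(self.effect_duration_years) < 1:
            raise ParameterError(
                f"effect_duration_years: {self.effect_duration_years} must be >= 1 or 'horizon'"
            )
        for arm in ARMS:
            if arm not in self.activity_transitions:
                raise ParameterError(f"activity_transitions: missing arm {arm!r}")
            self.activity_transitions[arm].validate()
        self.epidemiology.validate()
        self.payoffs.validate()

    def with_overrides(self, **overrides) -> "ModelParameters":
        """Return a copy with simple fields overridden.

        Valid keys: cohort_size, horizon_years, discount_rate_costs,
        discount_rate_effects, effect_duration_years, perspective,
        utility_source.
        """
        simple = {"cohort_size", "horizon_years", "discount_rate_costs",
                  "discount_rate_effects", "effect_duration_years"}
        payoff_keys = {"perspective", "utility_source"}
        changes: dict = {}
        payoff_changes: dict = {}
        for key, value in overrides.items():
            if key in simple:
                changes[key] = value
            elif key in payoff_keys:
                payoff_changes[key] = value
            else:
                raise ParameterError(f"override: unknown parameter {key!r}")
        params = dataclasses.replace(self, **changes)
        if payoff_changes:
            params = dataclasses.replace(
                params, payoffs=dataclasses.replace(params.payoffs, **payoff_changes))
        params.validate()
        return params


# ---------------------------------------------------------------------------
# Structured-text configuration (YAML)
# ---------------------------------------------------------------------------

_STATE_BY_NAME = {s.value: s for s in STATE_ORDER}


def _state(name: str, context: str) -> HealthState:
    try:
        return _STATE_BY_NAME[name]
    except KeyError:
        raise ParameterError(f"{context}: unknown state {name!r}") from None


def _check_keys(raw: Mapping, allowed: set[str], context: str) -> None:
    unknown = set(raw) - allowed
    if unknown:
        raise ParameterError(f"{context}: unknown keys {sorted(unknown)}")


def _specs_from(raw: Mapping, states, context: str) -> dict:
    _check_keys(raw, {s.value for s in states}, context)
    out = {}
    for s in states:
        if s.value not in raw:
            raise ParameterError(f"{context}.{s.value}: missing")
        out[s] = DistributionSpec.from_dict(f"{context}.{s.value}", raw[s.value])
    return out


def params_from_dict(doc: Mapping) -> ModelParameters:
    """Build and validate :class:`ModelParameters` from a parsed config."""
    _check_keys(doc, {"model", "activity_transitions", "epidemiology", "payoffs"}, "config")

    model = doc["model"]
    _check_keys(model, {"cohort_size", "horizon_years", "cycle_length_years",
                        "discount_rate_costs_annual", "discount_rate_effects_annual",
                        "effect_duration_years", "initial_activity_proportions"}, "model")
    init_raw = model["initial_activity_proportions"]
    _check_keys(init_raw, {s.value for s in ACTIVITY_STATES}, "model.initial_activity_proportions")
    initial = {_state(k, "initial_activity"): float(v) for k, v in init_raw.items()}

    blocks = {}
    at_raw = doc["activity_transitions"]
    _check_keys(at_raw, set(ARMS), "activity_transitions")
    for arm in ARMS:
        probs = {}
        arm_raw = at_raw[arm]
        _check_keys(arm_raw, {s.value for s in ACTIVITY_STATES}, f"activity_transitions.{arm}")
        for s in ACTIVITY_STATES:
            row = arm_raw[s.value]
            _check_keys(row, {t.value for t in ACTIVITY_STATES}, f"activity_transitions.{arm}.{s}")
            for t in ACTIVITY_STATES:
                probs[(s, t)] = DistributionSpec.from_dict(
                    f"activity_transitions.{arm}.{s}.{t}", row[t.value])
        blocks[arm] = ActivityTransitionBlock(arm=arm, probs=probs)

    epi_raw = doc["epidemiology"]
    _check_keys(epi_raw, {"disease_incidence_annual", "activity_mortality_annual",
                          "disease_mortality_annual"}, "epidemiology")
    incidence = {}
    for a in ACTIVITY_STATES:
        row = epi_raw["disease_incidence_annual"][a.value]
        _check_keys(row, {d.value for d in DISEASE_STATES}, f"epidemiology.disease_incidence.{a}")
        for d in DISEASE_STATES:
            incidence[(a, d)] = float(row[d.value])
    act_mort = {a: float(epi_raw["activity_mortality_annual"][a.value]) for a in ACTIVITY_STATES}
    dis_mort = {d: float(epi_raw["disease_mortality_annual"][d.value]) for d in DISEASE_STATES}
    epidemiology = EpidemiologyBlock(
        disease_incidence=incidence, activity_mortality=act_mort, disease_mortality=dis_mort)

    pay_raw = doc["payoffs"]
    _check_keys(pay_raw, {"perspective", "utility_source", "utilities_per_year",
                          "annual_costs_eur2017", "program_cost_eur"}, "payoffs")
    util_raw = pay_raw["utilities_per_year"]
    _check_keys(util_raw, {"trial", "literature", "disease"}, "payoffs.utilities_per_year")
    cost_raw = pay_raw["annual_costs_eur2017"]
    _check_keys(cost_raw, set(PERSPECTIVES), "payoffs.annual_costs_eur2017")
    payoffs = PayoffBlock(
        perspective=pay_raw["perspective"],
        utility_source=pay_raw["utility_source"],
        activity_utilities={
            source: _specs_from(util_raw[source], ACTIVITY_STATES,
                                f"payoffs.utilities_per_year.{source}")
            for source in UTILITY_SOURCES
        },
        disease_utilities=_specs_from(util_raw["disease"], DISEASE_STATES,
                                      "payoffs.utilities_per_year.disease"),
        activity_costs={
            persp: _specs_from(
                {k: v for k, v in cost_raw[persp].items()
                 if k in {s.value for s in ACTIVITY_STATES}},
                ACTIVITY_STATES, f"payoffs.annual_costs_eur2017.{persp}")
            for persp in PERSPECTIVES
        },
        disease_costs={
            persp: _specs_from(
                {k: v for k, v in cost_raw[persp].items()
                 if k in {s.value for s in DISEASE_STATES}},
                DISEASE_STATES, f"payoffs.annual_costs_eur2017.{persp}")
            for persp in PERSPECTIVES
        },
        program_cost=float(pay_raw["program_cost_eur"]),
    )

    params = ModelParameters(
        initial_activity=initial,
        cohort_size=int(model["cohort_size"]),
        horizon_years=int(model["horizon_years"]),
        cycle_length_years=int(model.get("cycle_length_years", 1)),
        discount_rate_costs=float(model["discount_rate_costs_annual"]),
        discount_rate_effects=float(model["discount_rate_effects_annual"]),
        effect_duration_years=(
            model.get("effect_duration_years", "horizon")
            if model.get("effect_duration_years", "horizon") == "horizon"
            else int(model["effect_duration_years"])),
        activity_transitions=blocks,
        epidemiology=epidemiology,
        payoffs=payoffs,
    )
    params.validate()
    return params


def params_to_dict(params: ModelParameters) -> dict:
    """Inverse of :func:`params_from_dict`; round-trips bit-exactly."""
    doc: dict = {
        "model": {
            "cohort_size": params.cohort_size,
            "horizon_years": params.horizon_years,
            "cycle_length_years": params.cycle_length_years,
            "discount_rate_costs_annual": params.discount_rate_costs,
            "discount_rate_effects_annual": params.discount_rate_effects,
            "effect_duration_years": params.effect_duration_years,
            "initial_activity_proportions": {
                a.value: params.initial_activity[a] for a in ACTIVITY_STATES},
        },
        "activity_transitions": {
            arm: {
                s.value: {
                    t.value: params.activity_transitions[arm].probs[(s, t)].to_dict()
                    for t in ACTIVITY_STATES}
                for s in ACTIVITY_STATES}
            for arm in ARMS},
        "epidemiology": {
            "disease_incidence_annual": {
                a.value: {d.value: params.epidemiology.disease_incidence[(a, d)]
                          for d in DISEASE_STATES}
                for a in ACTIVITY_STATES},
            "activity_mortality_annual": {
                a.value: params.epidemiology.activity_mortality[a] for a in ACTIVITY_STATES},
            "disease_mortality_annual": {
                d.value: params.epidemiology.disease_mortality[d] for d in DISEASE_STATES},
        },
        "payoffs": {
            "perspective": params.payoffs.perspective,
            "utility_source": params.payoffs.utility_source,
            "utilities_per_year": {
                "trial": {a.value: params.payoffs.activity_utilities["trial"][a].to_dict()
                          for a in ACTIVITY_STATES},
                "literature": {a.value: params.payoffs.activity_utilities["literature"][a].to_dict()
                               for a in ACTIVITY_STATES},
                "disease": {d.value: params.payoffs.disease_utilities[d].to_dict()
                            for d in DISEASE_STATES},
            },
            "annual_costs_eur2017": {
                persp: {
                    **{a.value: params.payoffs.activity_costs[persp][a].to_dict()
                       for a in ACTIVITY_STATES},
                    **{d.value: params.payoffs.disease_costs[persp][d].to_dict()
                       for d in DISEASE_STATES},
                }
                for persp in PERSPECTIVES},
            "program_cost_eur": params.payoffs.program_cost,
        },
    }
    return doc


def load_parameters(config_path: str | Path, overrides: Mapping | None = None) -> ModelParameters:
    """Load a YAML parameter file, apply overrides, validate."""
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    params = params_from_dict(doc)
    if overrides:
        params = params.with_overrides(**dict(overrides))
    return params


def save_parameters(params: ModelParameters, config_path: str | Path) -> None:
    with open(config_path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=False)


def builtin_fixture(perspective: str = "societal", utility_source: str = "trial") -> ModelParameters:
    """The packaged published parameter set for one analysis combination.

    ``(societal, trial)`` is the base case; the other combinations select the
    healthcare-perspective cost block and/or the literature utility block.
    """
    ref = importlib.resources.files("fitcea") / "data" / _REFERENCE_RESOURCE
    with importlib.resources.as_file(ref) as path:
        params = load_parameters(path)
    return params.with_overrides(perspective=perspective, utility_source=utility_source)


def parameter_table(params: ModelParameters) -> pd.DataFrame:
    """Flatten the parameter set to one row per entry (for audit/CSV export)."""
    rows = []

    def add(block, name, spec: DistributionSpec):
        rows.append({
            "block": block, "parameter": name, "point": spec.point,
            "distribution": spec.family,
            "param1": spec.param1 if spec.param1 is not None else "",
            "param2": spec.param2 if spec.param2 is not None else "",
        })

    for arm in ARMS:
        for s in ACTIVITY_STATES:
            for t in ACTIVITY_STATES:
                add(f"activity_transitions.{arm}", f"{s}->{t}",
                    params.activity_transitions[arm].probs[(s, t)])
    for a in ACTIVITY_STATES:
        for d in DISEASE_STATES:
            add("disease_incidence", f"{a}->{d}",
                DistributionSpec.fixed(params.epidemiology.disease_incidence[(a, d)]))
    for a in ACTIVITY_STATES:
        add("mortality", f"{a}->dead", DistributionSpec.fixed(params.epidemiology.activity_mortality[a]))
    for d in DISEASE_STATES:
        add("mortality", f"{d}->dead", DistributionSpec.fixed(params.epidemiology.disease_mortality[d]))
    for source in UTILITY_SOURCES:
        for a in ACTIVITY_STATES:
            add(f"utilities.{source}", str(a), params.payoffs.activity_utilities[source][a])
    for d in DISEASE_STATES:
        add("utilities.disease", str(d), params.payoffs.disease_utilities[d])
    for persp in PERSPECTIVES:
        for a in ACTIVITY_STATES:
            add(f"costs.{persp}", str(a), params.payoffs.activity_costs[persp][a])
        for d in DISEASE_STATES:
            add(f"costs.{persp}", str(d), params.payoffs.disease_costs[persp][d])
    add("costs", "program", DistributionSpec.fixed(params.payoffs.program_cost))
    return pd.DataFrame(rows)
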