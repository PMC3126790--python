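"""Univariate (tornado) sensitivity analysis.

Each scenario re-runs the full pipeline on a perturbed copy of the base
parameter set: +-25% multiplicative changes of named parameter groups, a
horizon switch (52 -> 12 weeks) and a perspective switch (societal ->
payer).  Perturbed probabilities are clamped to [0, 1] with a logged
warning.  The base parameter set is never modified; scenario runs are pure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import pandas as pd

from .cea import CEAResult, compare
from .costs import total_cost
from .engine import run_cohort
from .parameters import ConfigurationError, ParameterSet
from .qaly import arm_qaly_gain

log = logging.getLogger(__name__)

REFERENCE_ARM = "fesoterodine"
COMPARATOR_ARMS = ("tolterodine", "solifenacin")


@dataclass(frozen=True)
class Perturbation:
    """Multiplicative change of a set of parameter paths.

    Paths are dotted keys into the parameter set; ``*`` matches every key at
    that level.  ``probability`` marks paths whose perturbed value must stay
    in [0, 1] (clamped, with a warning).
    """

    paths: tuple[str, ...]
    factor: float
    probability: bool = False


@dataclass(frozen=True)
class Scenario:
    name: str
    perturbations: tuple[Perturbation, ...] = ()
    horizon_weeks: Optional[int] = None
    perspective: Optional[str] = None
    w12_continence_factor: Optional[float] = None
    w52_continence_factor: Optional[float] = None
    utility_increment_factor: Optional[float] = None


@dataclass(frozen=True)
class TornadoRow:
    scenario: str
    results: dict[str, CEAResult]  # comparator arm -> result


def _resolve(container, parts: list[str], prefix: str = ""):
    """Yield (parent, key, path) for every leaf a dotted path addresses."""
    key, rest = parts[0], parts[1:]
    if not isinstance(container, dict):
        raise ConfigurationError(f"path '{prefix}{key}' does not resolve")
    keys = list(container.keys()) if key == "*" else [key]
    for k in keys:
        if k not in container:
            raise ConfigurationError(f"unresolvable parameter path '{prefix}{k}'")
        if rest:
            yield from _resolve(container[k], rest, prefix=f"{prefix}{k}.")
        else:
            yield container, k, f"{prefix}{k}"


def _clamp_probability(value: float, path: str) -> float:
    if value < 0.0 or value > 1.0:
        clamped = min(max(value, 0.0), 1.0)
        log.warning("perturbed probability at %s = %.4f clamped to %.1f",
                    path, value, clamped)
        return clamped
    return value


def perturb_parameter_set(params: ParameterSet, scenario: Scenario) -> ParameterSet:
    """Apply a scenario to a copy of ``params``; the original is untouched."""
    doc = params.model_dump()

    for pert in scenario.perturbations:
        for path in pert.paths:
            for parent, key, full in _resolve(doc, path.split(".")):
                value = parent[key] * pert.factor
                if pert.probability:
                    value = _clamp_probability(value, full)
                parent[key] = value

    if scenario.w12_continence_factor is not None:
        _scale_w12_continence(doc, scenario.w12_continence_factor)
    if scenario.w52_continence_factor is not None:
        f = scenario.w52_continence_factor
        week = max(int(w) for w in doc["shared_persistence"]["remaining"])
        value = doc["shared_persistence"]["remaining"][week] * f
        doc["shared_persistence"]["remaining"][week] = _clamp_probability(
            value, f"shared_persistence.{week}")
    if scenario.utility_increment_factor is not None:
        _scale_utility_increments(doc, scenario.utility_increment_factor)

    if scenario.horizon_weeks is not None:
        doc["horizon_weeks"] = scenario.horizon_weeks
    if scenario.perspective is not None:
        doc["perspective"] = scenario.perspective

    return ParameterSet.model_validate(doc)


def _scale_w12_continence(doc: dict, factor: float) -> None:
    """Scale every arm's week-12 response fraction uniformly.

    Implemented through the engine's aggregate response multiplier rather
    than by clamping each conditional column at 1: per-cell clamping binds
    at different factors for different arms and silently reorders them,
    which is not what a uniform "% continent at week 12" perturbation means.
    """
    doc["w12_response_scale"] = doc.get("w12_response_scale", 1.0) * factor


def _scale_utility_increments(doc: dict, factor: float) -> None:
    """Scale the state-utility increments over the untreated baseline.

    Scaling the utilities themselves by +25% would push every state above 1
    and clamping would collapse all states to equal utility; perturbing the
    increments preserves the meaning of the scenario.
    """
    base = doc["utilities"]["u_untreated"]
    for fld in ("u_continent", "u_incontinent_on_rx"):
        value = base + factor * (doc["utilities"][fld] - base)
        doc["utilities"][fld] = _clamp_probability(value, f"utilities.{fld}")


def continent_share_perturbation(params: ParameterSet, factor: float) -> ParameterSet:
    """Scale every arm's week-12 response fractions by ``factor`` (clamped)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return perturb_parameter_set(params, Scenario(
        name=f"w12 continence x{factor}", w12_continence_factor=factor))


def run_scenario(params: ParameterSet, scenario: Scenario,
                 reference: str = REFERENCE_ARM,
                 comparators: tuple[str, ...] = COMPARATOR_ARMS,
                 ) -> dict[str, CEAResult]:
    """Full pipeline on the perturbed parameter set; base set unmodified."""
    perturbed = perturb_parameter_set(params, scenario)

    def arm_outcome(arm_id: str) -> tuple[float, float]:
        traj = run_cohort(arm_id, perturbed)
        cost = total_cost(traj, perturbed).total
        return cost, arm_qaly_gain(arm_id, perturbed, traj)

    ref = arm_outcome(reference)
    return {
        comp: compare(ref, arm_outcome(comp), ref_arm=reference, comp_arm=comp)
        for comp in comparators
    }


def tornado(params: ParameterSet, scenarios: Iterable[Scenario],
            reference: str = REFERENCE_ARM,
            comparators: tuple[str, ...] = COMPARATOR_ARMS) -> list[TornadoRow]:
    """One row per scenario, in the configured order (no deduplication)."""
    return [
        TornadoRow(s.name, run_scenario(params, s, reference, comparators))
        for s in scenarios
    ]


def tornado_frame(rows: list[TornadoRow]) -> pd.DataFrame:
    records = []
    for row in rows:
        rec: dict = {"scenario": row.scenario}
        for comp, res in row.results.items():
            rec[f"icer_vs_{comp}"] = res.icer_or_label
            rec[f"delta_cost_vs_{comp}"] = res.delta_cost
            rec[f"delta_qaly_vs_{comp}"] = res.delta_qaly
        records.append(rec)
    return pd.DataFrame(records)


def _pair(name: str, **kwargs) -> list[Scenario]:
    """Build the +25% / -25% pair for one parameter group."""
    out = []
    for sign, factor in (("+25%", 1.25), ("-25%", 0.75)):
        kw = {}
        for key, value in kwargs.items():
            if key == "perturbations":
                kw[key] = tuple(replace(p, factor=factor) for p in value)
            elif key.endswith("_factor"):
                kw[key] = factor
            else:
                kw[key] = value
        out.append(Scenario(name=f"{sign} {name}", **kw))
    return out


_COMORBIDITY_COST_PATHS = (
    "unit_costs.fracture_event", "unit_costs.skin_infection_episode",
    "unit_costs.uti_episode", "unit_costs.depression_per_patient_year",
    "unit_costs.nursing_home",
)
_MEDICAL_COST_PATHS = (
    "unit_costs.pad", "unit_costs.gp_visit", "unit_costs.specialist_visit",
    "unit_costs.lab_test", "unit_costs.constipation_per_day",
)
_COMORBIDITY_PROB_FIELDS = ("fracture_prob_6mo", "skin_prob_6mo", "uti_prob_6mo",
                            "depression_prob_annual")
_COMORBIDITY_RATE_FIELDS = ("skin_events_per_person", "uti_events_per_person",
                            "nursing_home_admissions_per_1000py")


def _comorbidity_rate_perturbations(statuses: tuple[str, ...]) -> tuple[Perturbation, ...]:
    probs = tuple(f"comorbidity.{s}.{f}" for s in statuses
                  for f in _COMORBIDITY_PROB_FIELDS)
    rates = tuple(f"comorbidity.{s}.{f}" for s in statuses
                  for f in _COMORBIDITY_RATE_FIELDS)
    return (Perturbation(probs, 1.0, probability=True), Perturbation(rates, 1.0))


def default_scenarios(titration_arms: tuple[str, ...] = ("fesoterodine", "solifenacin"),
                      ) -> list[Scenario]:
    """The published univariate grid: base case first, then every +-25% pair
    plus the horizon and perspective switches."""
    scenarios: list[Scenario] = [
        Scenario("base case (52 weeks, societal)"),
        Scenario("52 weeks, health-system perspective", perspective="payer"),
        Scenario("12 weeks, health-system perspective",
                 horizon_weeks=12, perspective="payer"),
        Scenario("12 weeks, societal perspective", horizon_weeks=12),
    ]
    scenarios += _pair("OAB comorbidity costs", perturbations=(
        Perturbation(_COMORBIDITY_COST_PATHS, 1.0),))
    scenarios += _pair(
        "comorbidity rates, continent patients",
        perturbations=_comorbidity_rate_perturbations(("controlled",)))
    scenarios += _pair(
        "comorbidity rates, incontinent patients",
        perturbations=_comorbidity_rate_perturbations(
            ("uncontrolled_on_rx", "untreated")))
    scenarios += _pair("utility estimates", utility_increment_factor=1.0)
    scenarios += _pair("responders titrating at week 4", perturbations=(
        Perturbation(tuple(f"titration.{a}.frac_responders_titrate"
                           for a in titration_arms), 1.0, probability=True),))
    scenarios += _pair("non-responders staying on start dose at week 4",
                       perturbations=(Perturbation(
                           tuple(f"titration.{a}.frac_nonresponders_titrate"
                                 for a in titration_arms), 1.0, probability=True),))
    scenarios += _pair("% continent patients at week 12", w12_continence_factor=1.0)
    scenarios += _pair("% continent patients at week 52", w52_continence_factor=1.0)
    scenarios += _pair("medical services costs", perturbations=(
        Perturbation(_MEDICAL_COST_PATHS, 1.0),))
    scenarios += _pair("% of incontinent patients using pads", perturbations=(
        Perturbation(("resource_use.uncontrolled_on_rx.frac_using_pads",
                      "resource_use.untreated.frac_using_pads"), 1.0,
                     probability=True),))
    scenarios += _pair("pads per day for incontinent patients", perturbations=(
        Perturbation(("resource_use.uncontrolled_on_rx.pads_per_day",
                      "resource_use.untreated.pads_per_day"), 1.0),))
    scenarios += _pair("GP visits per month", perturbations=(
        Perturbation(("resource_use.*.gp_visits_per_month",), 1.0),))
    scenarios += _pair("specialist visits per month", perturbations=(
        Perturbation(("resource_use.*.specialist_visits_per_month",), 1.0),))
    scenarios += _pair("lab tests per month", perturbations=(
        Perturbation(("resource_use.*.lab_tests_per_month",), 1.0),))
    scenarios += _pair("decrease in hours worked due to incontinence",
                       perturbations=(Perturbation(
                           ("productivity.incontinence_hours_reduction",
                            "productivity.hours_reduction_female",
                            "productivity.hours_reduction_male"), 1.0,
                           probability=True),))
    scenarios += _pair("reduced daytime productivity due to nocturia",
                       perturbations=(Perturbation(
                           ("productivity.nocturia_impairment",), 1.0,
                           probability=True),))
    scenarios += _pair("% employed in population", perturbations=(
        Perturbation(("productivity.frac_employed",), 1.0, probability=True),))
    scenarios += _pair("average hourly wage", perturbations=(
        Perturbation(("productivity.wage_per_hour",), 1.0),))
    return scenarios
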