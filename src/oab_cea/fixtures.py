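"""Packaged base case, random parameter-set generation, and the
individual-level microsimulation oracle.

``paper_basecase`` returns the packaged parameter fixture (the published
base case).  ``random_parameter_set`` draws valid parameter sets for
property tests: every draw respects the type invariants by construction
(sorted persistence draws, week-12 marginals derived from the drawn
conditionals, event counts at least as large as event probabilities).
``microsim`` simulates individual patients through the same decision tree
the cohort engine evaluates in expectation, and is used as an independent
statistical oracle for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .engine import Occupancy, OccupancyTrajectory
from .parameters import ParameterSet, parameter_set_from_dict

# arm structure of the generated sets (mirrors the packaged base case)
ARM_SKELETON: dict[str, tuple[str, str | None]] = {
    "placebo": ("std", None),
    "fesoterodine": ("4mg", "8mg"),
    "tolterodine": ("4mg", None),
    "solifenacin": ("5mg", "10mg"),
}

_STATUSES = ("controlled", "uncontrolled_on_rx", "untreated")


def paper_basecase() -> ParameterSet:
    """The packaged published base case (validated on load)."""
    text = resources.files("oab_cea.data").joinpath("paper_basecase.yaml").read_text()
    return parameter_set_from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class GenerationRanges:
    """Uniform draw bounds for random parameter sets.

    ``overrides`` maps a parameter path (internal fraction scale) to an
    explicit (low, high) bound; any path not overridden uses the family
    default.  The seed fully determines the output: a single root seed is
    streamed to independent sub-generators per parameter family, so adding
    a family does not shift existing draws.
    """

    seed: int = 0
    overrides: Mapping[str, tuple[float, float]] = dc_field(default_factory=dict)

    @classmethod
    def degenerate(cls, params: ParameterSet, seed: int = 0) -> "GenerationRanges":
        """Point ranges pinned at an existing parameter set's values."""
        overrides: dict[str, tuple[float, float]] = {}

        def pin(path: str, value: float) -> None:
            overrides[path] = (value, value)

        for arm_id, arm in params.arms.items():
            for dose, eff in arm.doses.items():
                base = f"arms.{arm_id}.doses.{dose}"
                for fld in ("response_w2", "response_w8", "response_w12",
                            "cond_w12_given_w8resp", "cond_w12_given_w8nonresp",
                            "nocturia_resolution_w12", "constipation_rate"):
                    pin(f"{base}.{fld}", getattr(eff, fld))
        for arm_id, curve in params.persistence.items():
            pin(f"persistence.{arm_id}.8", curve.at(8))
        for week in (12, 24, 52):
            pin(f"shared_persistence.{week}", params.shared_persistence.at(week))
        for arm_id, pol in params.titration.items():
            pin(f"titration.{arm_id}.frac_responders_titrate",
                pol.frac_responders_titrate)
            pin(f"titration.{arm_id}.frac_nonresponders_titrate",
                pol.frac_nonresponders_titrate)
        uc = params.unit_costs
        for fld in ("pad", "gp_visit", "specialist_visit", "lab_test",
                    "constipation_per_day", "fracture_event",
                    "skin_infection_episode", "uti_episode",
                    "depression_per_patient_year", "nursing_home"):
            pin(f"unit_costs.{fld}", getattr(uc, fld))
        for arm_id, prices in uc.drug_per_day.items():
            for dose, price in prices.items():
                pin(f"unit_costs.drug_per_day.{arm_id}.{dose}", price)
        for status in _STATUSES:
            use = getattr(params.resource_use, status)
            for fld in ("frac_using_pads", "pads_per_day", "gp_visits_per_month",
                        "specialist_visits_per_month", "lab_tests_per_month"):
                pin(f"resource_use.{status}.{fld}", getattr(use, fld))
            com = params.comorbidity.for_status(status)
            for fld in ("fracture_prob_6mo", "skin_prob_6mo", "skin_events_per_person",
                        "uti_prob_6mo", "uti_events_per_person",
                        "depression_prob_annual", "nursing_home_admissions_per_1000py"):
                pin(f"comorbidity.{status}.{fld}", getattr(com, fld))
        pin("utilities.u_continent", params.utilities.u_continent)
        pin("utilities.u_incontinent_on_rx", params.utilities.u_incontinent_on_rx)
        pin("utilities.u_untreated", params.utilities.u_untreated)
        dec = params.comorbidity.utility_decrements
        pin("utility_decrements.fracture", dec.fracture)
        pin("utility_decrements.depression", dec.depression)
        prod = params.productivity
        for fld in ("wage_per_hour", "hours_per_week", "frac_employed",
                    "incontinence_hours_reduction", "hours_reduction_female",
                    "hours_reduction_male", "frac_female", "nocturia_impairment",
                    "baseline_nocturia_prevalence"):
            pin(f"productivity.{fld}", getattr(prod, fld))
        return cls(seed=seed, overrides=overrides)


_FAMILIES = ("efficacy", "persistence", "titration", "costs",
             "resource", "comorbidity", "utilities", "productivity")


class _Drawer:
    def __init__(self, rng: np.random.Generator,
                 overrides: Mapping[str, tuple[float, float]]):
        self.rng = rng
        self.overrides = overrides

    def __call__(self, path: str, lo: float, hi: float) -> float:
        lo, hi = self.overrides.get(path, (lo, hi))
        if hi < lo:
            raise ValueError(f"infeasible range for {path}: ({lo}, {hi})")
        return float(self.rng.uniform(lo, hi)) if hi > lo else float(lo)


def random_parameter_set(ranges: GenerationRanges | None = None, *,
                         seed: int | None = None) -> ParameterSet:
    """Draw a parameter set that passes validation by construction."""
    if ranges is None:
        ranges = GenerationRanges(seed=seed if seed is not None else 0)
    streams = np.random.SeedSequence(ranges.seed).spawn(len(_FAMILIES))
    draw = {name: _Drawer(np.random.default_rng(stream), ranges.overrides)
            for name, stream in zip(_FAMILIES, streams)}

    doc: dict = {"arms": {}, "persistence": {}, "titration": {}}
    d = draw["efficacy"]
    for arm_id, (start, high) in ARM_SKELETON.items():
        doses = {}
        for dose in filter(None, (start, high)):
            base = f"arms.{arm_id}.doses.{dose}"
            r8 = d(f"{base}.response_w8", 0.10, 0.80)
            cond_r = d(f"{base}.cond_w12_given_w8resp", 0.40, 0.99)
            # consistent by construction unless the range pins it explicitly
            if f"{base}.response_w12" in ranges.overrides:
                r12 = d(f"{base}.response_w12", 0.0, 1.0)
            else:
                r12 = cond_r * r8
            doses[dose] = {
                "response_w2": d(f"{base}.response_w2", 0.05, r8),
                "response_w8": r8,
                "response_w12": r12,
                "cond_w12_given_w8resp": cond_r,
                "cond_w12_given_w8nonresp": d(f"{base}.cond_w12_given_w8nonresp",
                                              0.01, 0.40),
                "nocturia_resolution_w12": d(f"{base}.nocturia_resolution_w12",
                                             0.20, 0.95),
                "constipation_rate": d(f"{base}.constipation_rate", 0.0, 0.15),
            }
        doc["arms"][arm_id] = {"arm_id": arm_id, "start_dose": start,
                               "high_dose": high, "doses": doses}

    d = draw["persistence"]
    shared = sorted(
        (d(f"shared_persistence.{week}", 0.30, 0.95) for week in (12, 24, 52)),
        reverse=True)
    shared = dict(zip((12, 24, 52), shared))
    doc["shared_persistence"] = {"remaining": shared}
    for arm_id in ARM_SKELETON:
        w8 = d(f"persistence.{arm_id}.8", shared[12], 1.0)
        doc["persistence"][arm_id] = {"remaining": {2: 1.0, 8: max(w8, shared[12])}}

    d = draw["titration"]
    for arm_id, (_, high) in ARM_SKELETON.items():
        if high is None:
            doc["titration"][arm_id] = {"frac_responders_titrate": 0.0,
                                        "frac_nonresponders_titrate": 0.0}
        else:
            doc["titration"][arm_id] = {
                "frac_responders_titrate":
                    d(f"titration.{arm_id}.frac_responders_titrate", 0.0, 1.0),
                "frac_nonresponders_titrate":
                    d(f"titration.{arm_id}.frac_nonresponders_titrate", 0.0, 1.0),
            }

    d = draw["costs"]
    doc["unit_costs"] = {
        "pad": d("unit_costs.pad", 0.0, 2.0),
        "gp_visit": d("unit_costs.gp_visit", 0.0, 100.0),
        "specialist_visit": d("unit_costs.specialist_visit", 0.0, 200.0),
        "lab_test": d("unit_costs.lab_test", 0.0, 20.0),
        "constipation_per_day": d("unit_costs.constipation_per_day", 0.0, 1.0),
        "fracture_event": d("unit_costs.fracture_event", 0.0, 10_000.0),
        "skin_infection_episode": d("unit_costs.skin_infection_episode", 0.0, 200.0),
        "uti_episode": d("unit_costs.uti_episode", 0.0, 200.0),
        "depression_per_patient_year": d("unit_costs.depression_per_patient_year",
                                         0.0, 5_000.0),
        "nursing_home": d("unit_costs.nursing_home", 0.0, 30_000.0),
        "drug_per_day": {
            arm_id: {dose: d(f"unit_costs.drug_per_day.{arm_id}.{dose}", 0.0, 5.0)
                     for dose in filter(None, skeleton)}
            for arm_id, skeleton in ARM_SKELETON.items()
        },
    }

    d = draw["resource"]
    doc["resource_use"] = {
        status: {
            "frac_using_pads": d(f"resource_use.{status}.frac_using_pads", 0.0, 1.0),
            "pads_per_day": d(f"resource_use.{status}.pads_per_day", 0.0, 8.0),
            "gp_visits_per_month": d(f"resource_use.{status}.gp_visits_per_month",
                                     0.0, 1.0),
            "specialist_visits_per_month":
                d(f"resource_use.{status}.specialist_visits_per_month", 0.0, 1.0),
            "lab_tests_per_month": d(f"resource_use.{status}.lab_tests_per_month",
                                     0.0, 0.5),
        }
        for status in _STATUSES
    }

    d = draw["comorbidity"]
    comorbidity: dict = {}
    for status in _STATUSES:
        base = f"comorbidity.{status}"
        skin_p = d(f"{base}.skin_prob_6mo", 0.0, 0.5)
        uti_p = d(f"{base}.uti_prob_6mo", 0.0, 0.5)
        if f"{base}.skin_events_per_person" in ranges.overrides:
            skin_e = d(f"{base}.skin_events_per_person", 0.0, 5.0)
        else:
            skin_e = skin_p * d(f"{base}.skin_events_multiplier", 1.0, 3.0)
        if f"{base}.uti_events_per_person" in ranges.overrides:
            uti_e = d(f"{base}.uti_events_per_person", 0.0, 5.0)
        else:
            uti_e = uti_p * d(f"{base}.uti_events_multiplier", 1.0, 3.0)
        comorbidity[status] = {
            "fracture_prob_6mo": d(f"{base}.fracture_prob_6mo", 0.0, 0.2),
            "skin_prob_6mo": skin_p,
            "skin_events_per_person": skin_e,
            "uti_prob_6mo": uti_p,
            "uti_events_per_person": uti_e,
            "depression_prob_annual": d(f"{base}.depression_prob_annual", 0.0, 0.5),
            "nursing_home_admissions_per_1000py":
                d(f"{base}.nursing_home_admissions_per_1000py", 0.0, 200.0),
        }
    comorbidity["depression_by_sex"] = None
    comorbidity["nursing_home_by_sex"] = None

    d = draw["utilities"]
    u = sorted(d(f"utilities.draw_{i}", 0.5, 1.0) for i in range(3))
    if "utilities.u_untreated" in ranges.overrides:
        u = [d("utilities.u_untreated", 0.0, 1.0),
             d("utilities.u_incontinent_on_rx", 0.0, 1.0),
             d("utilities.u_continent", 0.0, 1.0)]
    comorbidity["utility_decrements"] = {
        "fracture": d("utility_decrements.fracture", 0.0, 0.3),
        "depression": d("utility_decrements.depression", 0.0, 0.6),
        "nursing_home": None,
    }
    doc["comorbidity"] = comorbidity
    doc["utilities"] = {"u_untreated": u[0], "u_incontinent_on_rx": u[1],
                        "u_continent": u[2]}

    d = draw["productivity"]
    doc["productivity"] = {
        "wage_per_hour": d("productivity.wage_per_hour", 5.0, 30.0),
        "hours_per_week": d("productivity.hours_per_week", 20.0, 50.0),
        "frac_employed": d("productivity.frac_employed", 0.2, 0.9),
        "incontinence_hours_reduction":
            d("productivity.incontinence_hours_reduction", 0.0, 0.5),
        "hours_reduction_female": d("productivity.hours_reduction_female", 0.0, 0.5),
        "hours_reduction_male": d("productivity.hours_reduction_male", 0.0, 0.5),
        "frac_female": d("productivity.frac_female", 0.0, 1.0),
        "hours_reduction_mode": "sex_weighted",
        "nocturia_impairment": d("productivity.nocturia_impairment", 0.0, 0.3),
        "baseline_nocturia_prevalence":
            d("productivity.baseline_nocturia_prevalence", 0.0, 1.0),
    }

    params = ParameterSet.model_validate(doc)
    from .parameters import ParameterValidationError, validate

    report = validate(params)
    if report:  # pragma: no cover - generator guarantees consistency
        raise ParameterValidationError(report)
    return params


def microsim(arm_id: str, params: ParameterSet, n: int,
             seed: int | np.random.SeedSequence = 0) -> OccupancyTrajectory:
    """Individual-level simulation of ``n`` patients through the tree.

    Each patient draws a Bernoulli week-8-proxy response at the start dose,
    a Bernoulli titration decision per the policy, a Bernoulli week-12
    response with the branch-appropriate conditional, and survives the
    persistence curve via a single latent uniform compared against the
    (non-increasing) remaining fractions, which makes discontinuation
    monotone over time within a patient.  Returns empirical state fractions
    in the same trajectory container the cohort engine produces.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    arm = params.arms[arm_id]
    policy = params.titration[arm_id]
    rng = np.random.default_rng(seed)

    start, high = arm.start_dose, arm.high_dose
    resp8 = rng.random(n) < arm.doses[start].response_w8
    if high is not None:
        t_prob = np.where(resp8, policy.frac_responders_titrate,
                          policy.frac_nonresponders_titrate)
        titrated = rng.random(n) < t_prob
    else:
        titrated = np.zeros(n, dtype=bool)
    doses = [start, high if high is not None else start]
    dose_ix = titrated.astype(int)

    cond = np.empty(n)
    for ix, dose in enumerate(doses):
        eff = arm.doses[dose]
        mask = dose_ix == ix
        cond[mask & resp8] = eff.cond_w12_given_w8resp
        cond[mask & ~resp8] = eff.cond_w12_given_w8nonresp
        if high is None:
            break
    resp12 = rng.random(n) < np.minimum(cond * params.w12_response_scale, 1.0)

    u_late = rng.random(n)       # shared persistence from week 12 on
    alive8 = rng.random(n) < params.persistence_at(arm_id, 8)

    def empirical(week: int) -> Occupancy:
        if week == 8:
            on_rx, cont = alive8, resp8
        else:
            on_rx = u_late < params.persistence_at(arm_id, week)
            cont = resp12
            if week > 12:
                on_rx = on_rx & resp12
        cont_by_dose: dict[str, float] = {}
        incont_by_dose: dict[str, float] = {}
        for ix in range(2 if high is not None else 1):
            mask = on_rx & (dose_ix == ix)
            cont_by_dose[doses[ix]] = float(np.mean(mask & cont))
            inc = float(np.mean(mask & ~cont))
            if week > 12:
                inc = 0.0
            incont_by_dose[doses[ix]] = inc
        total_on = sum(cont_by_dose.values()) + sum(incont_by_dose.values())
        return Occupancy(cont_by_dose, incont_by_dose, 1.0 - total_on)

    checkpoints = {week: empirical(week) for week in (8, 12, 24, 52)}
    return OccupancyTrajectory(arm_id=arm_id, checkpoints=checkpoints,
                               response_w12=float(np.mean(resp12)))
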