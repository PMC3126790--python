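"""Model inputs: domain types, loading, derivation and validation.

Every input of the decision-tree model lives in a single validated
:class:`ParameterSet`: per-arm response probabilities at the scheduled
checkpoint weeks, the persistence (discontinuation) curve, the week-4
titration policy, unit costs, status-conditional resource use and
comorbidity rates, state utilities and productivity inputs.

Probability-like quantities are stored as fractions internally.  The
on-disk parameter file (YAML, mirroring the source tables section by
section) keeps the tables' two-decimal percent precision; the loader
converts between the two representations losslessly.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class ParameterError(ValueError):
    """Base class for parameter-file problems."""


class ConfigurationError(ParameterError):
    """A required key is missing or a reference does not resolve."""


class ParameterValidationError(ParameterError):
    """One or more invariants are violated; carries the full report."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "; ".join(str(v) for v in violations)
        super().__init__(f"{len(violations)} parameter violation(s): {lines}")


class Violation(BaseModel):
    """A single broken invariant, addressed by parameter path."""

    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.message}"


Fraction = Field(ge=0.0, le=1.0)


class _Model(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class DoseEfficacy(_Model):
    """Response and tolerability probabilities for one dose of one arm.

    ``response_w*`` are marginal fractions of starters continent
    (<1 urge incontinence episode/24 h) at the trial checkpoints.  The two
    conditionals drive the week-12 reassessment given week-8-proxy status.
    """

    response_w2: float = Fraction
    response_w8: float = Fraction
    response_w12: float = Fraction
    cond_w12_given_w8resp: float = Fraction
    cond_w12_given_w8nonresp: float = Fraction
    nocturia_resolution_w12: float = Fraction
    constipation_rate: float = Fraction


class ArmEfficacy(_Model):
    arm_id: str
    start_dose: str
    high_dose: Optional[str] = None
    doses: dict[str, DoseEfficacy]

    @model_validator(mode="after")
    def _doses_resolve(self) -> "ArmEfficacy":
        for label in filter(None, (self.start_dose, self.high_dose)):
            if label not in self.doses:
                raise ValueError(f"dose '{label}' of arm '{self.arm_id}' has no efficacy entry")
        return self


class PersistenceCurve(_Model):
    """Fraction of starters still on therapy at each checkpoint week."""

    remaining: dict[int, float]

    @model_validator(mode="after")
    def _in_range_and_monotone(self) -> "PersistenceCurve":
        prev = 1.0 + 1e-12
        for week in sorted(self.remaining):
            value = self.remaining[week]
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"persistence at week {week} outside [0, 1]")
            if value > prev + 1e-12:
                raise ValueError(f"persistence increases between weeks (week {week})")
            prev = value
        return self

    def at(self, week: int) -> float:
        try:
            return self.remaining[week]
        except KeyError:
            raise ConfigurationError(f"no persistence value at week {week}") from None


class TitrationPolicy(_Model):
    frac_responders_titrate: float = Fraction
    frac_nonresponders_titrate: float = Fraction


class UnitCosts(_Model):
    pad: float = Field(ge=0)
    gp_visit: float = Field(ge=0)
    specialist_visit: float = Field(ge=0)
    lab_test: float = Field(ge=0)
    constipation_per_day: float = Field(ge=0)
    fracture_event: float = Field(ge=0)
    skin_infection_episode: float = Field(ge=0)
    uti_episode: float = Field(ge=0)
    depression_per_patient_year: float = Field(ge=0)
    nursing_home: float = Field(ge=0)
    drug_per_day: dict[str, dict[str, float]]

    @model_validator(mode="after")
    def _prices_non_negative(self) -> "UnitCosts":
        for arm, prices in self.drug_per_day.items():
            for dose, price in prices.items():
                if price < 0:
                    raise ValueError(f"negative drug price for {arm}/{dose}")
        return self


class StatusResourceUse(_Model):
    frac_using_pads: float = Fraction
    pads_per_day: float = Field(ge=0)
    gp_visits_per_month: float = Field(ge=0)
    specialist_visits_per_month: float = Field(ge=0)
    lab_tests_per_month: float = Field(ge=0)


class ResourceUse(_Model):
    controlled: StatusResourceUse
    uncontrolled_on_rx: StatusResourceUse
    untreated: StatusResourceUse


class StatusComorbidity(_Model):
    """Comorbidity incidence for one responder/treatment status.

    Skin-infection and UTI probabilities and expected event counts refer to
    the source's 6-month observation window; depression is an annual
    probability and nursing-home admissions an annual rate per 1000
    patient-years.
    """

    fracture_prob_6mo: float = Fraction
    skin_prob_6mo: float = Fraction
    skin_events_per_person: float = Field(ge=0)
    uti_prob_6mo: float = Fraction
    uti_events_per_person: float = Field(ge=0)
    depression_prob_annual: float = Fraction
    nursing_home_admissions_per_1000py: float = Field(ge=0)


class SexRates(_Model):
    women: float = Field(ge=0)
    men: float = Field(ge=0)


class BySex(_Model):
    frac_female: float = Fraction
    controlled: SexRates
    uncontrolled: SexRates


class UtilityDecrements(_Model):
    """Relative utility decrease while a comorbid condition is present."""

    fracture: float = Fraction
    depression: float = Fraction
    nursing_home: Optional[float] = Field(default=None, ge=0.0, le=1.0)

    @property
    def nursing_home_or_zero(self) -> float:
        return 0.0 if self.nursing_home is None else self.nursing_home


class ComorbidityProfile(_Model):
    controlled: StatusComorbidity
    uncontrolled_on_rx: StatusComorbidity
    untreated: StatusComorbidity
    depression_by_sex: Optional[BySex] = None
    nursing_home_by_sex: Optional[BySex] = None
    utility_decrements: UtilityDecrements

    def for_status(self, status: str) -> StatusComorbidity:
        return getattr(self, status)


class UtilitySet(_Model):
    u_continent: float = Fraction
    u_incontinent_on_rx: float = Fraction
    u_untreated: float = Fraction

    def for_state(self, state: str) -> float:
        return {
            "continent": self.u_continent,
            "incontinent_on_rx": self.u_incontinent_on_rx,
            "untreated": self.u_untreated,
        }[state]


class ProductivityInputs(_Model):
    """Inputs of the two indirect-cost channels.

    The incontinence channel values hours not worked by employed incontinent
    patients; the nocturia channel values reduced on-the-job productivity of
    treated patients whose baseline nocturia resolves.  ``hours_reduction_mode``
    selects whether the uniform printed hours reduction or the sex-weighted
    reduction (female/male impacts weighted by the cohort's female share) is
    applied; see the methods note for why the sex-weighted variant is the
    packaged default.
    """

    wage_per_hour: float = Field(ge=0)
    hours_per_week: float = Field(ge=0)
    frac_employed: float = Fraction
    incontinence_hours_reduction: float = Fraction
    hours_reduction_female: float = Fraction
    hours_reduction_male: float = Fraction
    frac_female: float = Fraction
    hours_reduction_mode: Literal["sex_weighted", "uniform"] = "sex_weighted"
    nocturia_impairment: float = Fraction
    baseline_nocturia_prevalence: float = Fraction

    @property
    def effective_hours_reduction(self) -> float:
        if self.hours_reduction_mode == "uniform":
            return self.incontinence_hours_reduction
        return (
            self.frac_female * self.hours_reduction_female
            + (1.0 - self.frac_female) * self.hours_reduction_male
        )


class ParameterSet(_Model):
    """The complete, validated input set of the model."""

    arms: dict[str, ArmEfficacy]
    persistence: dict[str, PersistenceCurve]
    shared_persistence: PersistenceCurve
    titration: dict[str, TitrationPolicy]
    unit_costs: UnitCosts
    resource_use: ResourceUse
    comorbidity: ComorbidityProfile
    utilities: UtilitySet
    productivity: ProductivityInputs
    horizon_weeks: Literal[12, 52] = 52
    perspective: Literal["societal", "payer"] = "societal"
    decrements_enabled: bool = False
    annualization_factor: float = Field(default=2.0, gt=0)
    # uniform multiplier on every arm's week-12 response fraction (sensitivity
    # knob for the "% continent at week 12" scenarios); the aggregate response
    # is capped at 1 inside the engine
    w12_response_scale: float = Field(default=1.0, gt=0)

    @model_validator(mode="after")
    def _references_resolve(self) -> "ParameterSet":
        for arm_id, arm in self.arms.items():
            if arm.arm_id != arm_id:
                raise ValueError(f"arm key '{arm_id}' does not match arm_id '{arm.arm_id}'")
            if arm_id not in self.persistence:
                raise ValueError(f"arm '{arm_id}' has no persistence curve")
            if arm_id not in self.titration:
                raise ValueError(f"arm '{arm_id}' has no titration policy")
            prices = self.unit_costs.drug_per_day.get(arm_id)
            if prices is None:
                raise ValueError(f"arm '{arm_id}' has no drug prices")
            for dose in arm.doses:
                if dose not in prices:
                    raise ValueError(f"no drug price for {arm_id}/{dose}")
        return self

    def persistence_at(self, arm_id: str, week: int) -> float:
        """Arm-specific persistence up to week 8, shared curve from week 12 on."""
        if week in self.shared_persistence.remaining:
            return self.shared_persistence.at(week)
        return self.persistence[arm_id].at(week)


# --------------------------------------------------------------------------
# derivation operations

def scale_efficacy_by_rr(placebo: ArmEfficacy, rr: float, *, arm_id: str,
                         dose: str) -> DoseEfficacy:
    """Derive one comparator dose row from the placebo row and a relative risk.

    The week-2/8/12 marginals and the week-12-given-week-8-nonresponse
    conditional are the placebo values multiplied by ``rr``; the
    week-12-given-week-8-response conditional is copied unscaled (the source
    marks it "equal to placebo").  Results are rounded to the parameter file's
    two-decimal percent convention.
    """
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    src = placebo.doses[placebo.start_dose]

    def scaled(value: float) -> float:
        out = value * rr
        if out > 1.0:
            raise ValueError(
                f"scaling {value:.4f} by rr={rr} for {arm_id}/{dose} exceeds 1"
            )
        return _round_percent(out)

    return DoseEfficacy(
        response_w2=scaled(src.response_w2),
        response_w8=scaled(src.response_w8),
        response_w12=scaled(src.response_w12),
        cond_w12_given_w8resp=_round_percent(src.cond_w12_given_w8resp),
        cond_w12_given_w8nonresp=scaled(src.cond_w12_given_w8nonresp),
        nocturia_resolution_w12=src.nocturia_resolution_w12,
        constipation_rate=src.constipation_rate,
    )


def _round_percent(fraction: float) -> float:
    """Round a fraction to the file's two-decimal percent precision (half up).

    A first quantization at six percent-decimals removes binary floating
    point noise (e.g. 0.2099 * 1.5 = 0.31484999...) so that exact decimal
    half-way cases round the way the source tables do.
    """
    pct = (Decimal(repr(fraction)) * Decimal(100)).quantize(
        Decimal("0.000001"), rounding=ROUND_HALF_UP)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)) / 100.0


def conditional_from_marginals(response_w8: float, response_w12: float) -> float:
    """Week-12 response probability given week-8 response, from the marginals.

    The source's W12|W8 column equals the ratio of the two marginals for
    every arm; values above 1 indicate inconsistent inputs and raise.
    """
    if response_w8 <= 0:
        raise ZeroDivisionError("conditional undefined: response_w8 is zero")
    ratio = response_w12 / response_w8
    if ratio > 1.0 + 1e-9:
        raise ValueError(
            f"response_w12 ({response_w12}) exceeds response_w8 ({response_w8})"
        )
    return min(ratio, 1.0)


def events_per_affected(events_per_person: float, prob_any: float) -> float:
    """Expected number of events among patients experiencing at least one.

    ``events_per_person`` is the expectation over the whole population and
    ``prob_any`` the probability of at least one event in the same window, so
    the conditional expectation is their ratio.
    """
    if prob_any <= 0:
        if events_per_person > 0:
            raise ValueError("events occur but the probability of any event is zero")
        return 0.0
    return events_per_person / prob_any


# --------------------------------------------------------------------------
# validation

CONSISTENCY_TOL = 0.005  # rounding band for cond * w8 == w12


def validate(params: ParameterSet) -> list[Violation]:
    """Cross-field invariant report; empty for a consistent parameter set.

    Field-level range checks are enforced at construction time by the types
    themselves; this reports the relational invariants: the conditional /
    marginal consistency band, persistence monotonicity across the per-arm /
    shared junction, event counts at least as large as event probabilities,
    and titration policies that are zero for single-dose arms.
    """
    violations: list[Violation] = []

    for arm_id, arm in params.arms.items():
        for dose, eff in arm.doses.items():
            product = eff.cond_w12_given_w8resp * eff.response_w8
            if abs(product - eff.response_w12) > CONSISTENCY_TOL:
                violations.append(Violation(
                    path=f"arms.{arm_id}.doses.{dose}",
                    message=(
                        "cond_w12_given_w8resp * response_w8 = "
                        f"{product:.4f} differs from response_w12 = "
                        f"{eff.response_w12:.4f} by more than {CONSISTENCY_TOL}"
                    ),
                ))
        if arm.high_dose is None:
            policy = params.titration.get(arm_id)
            if policy is not None and (
                policy.frac_responders_titrate or policy.frac_nonresponders_titrate
            ):
                violations.append(Violation(
                    path=f"titration.{arm_id}",
                    message="single-dose arm must have zero titration fractions",
                ))

    for arm_id, curve in params.persistence.items():
        last_week = max(curve.remaining)
        if params.shared_persistence.remaining:
            first_shared = min(params.shared_persistence.remaining)
            if params.shared_persistence.at(first_shared) > curve.at(last_week) + 1e-12:
                violations.append(Violation(
                    path=f"persistence.{arm_id}",
                    message=(
                        f"shared persistence at week {first_shared} exceeds the "
                        f"arm value at week {last_week}"
                    ),
                ))

    for status in ("controlled", "uncontrolled_on_rx", "untreated"):
        com = params.comorbidity.for_status(status)
        for prefix in ("skin", "uti"):
            prob = getattr(com, f"{prefix}_prob_6mo")
            events = getattr(com, f"{prefix}_events_per_person")
            if prob > 0 and events < prob - 1e-12:
                violations.append(Violation(
                    path=f"comorbidity.{status}.{prefix}_events_per_person",
                    message=(
                        f"expected events ({events}) below the probability of "
                        f"at least one event ({prob})"
                    ),
                ))

    return violations


# --------------------------------------------------------------------------
# file I/O

_PCT = 100.0

_EFFICACY_FIELDS = (
    "response_w2", "response_w8", "response_w12",
    "cond_w12_given_w8resp", "cond_w12_given_w8nonresp",
    "nocturia_resolution_w12", "constipation_rate",
)
_COMORBIDITY_PCT_FIELDS = (
    "fracture_prob_6mo", "skin_prob_6mo", "uti_prob_6mo", "depression_prob_annual",
)
_PRODUCTIVITY_PCT_FIELDS = (
    "frac_employed", "incontinence_hours_reduction", "hours_reduction_female",
    "hours_reduction_male", "frac_female", "nocturia_impairment",
    "baseline_nocturia_prevalence",
)


def _require(mapping: dict, key: str, context: str):
    if not isinstance(mapping, dict) or key not in mapping:
        raise ConfigurationError(f"missing key '{key}' in {context}")
    return mapping[key]


def _file_dict_to_internal(doc: dict) -> dict:
    """Convert the percent-precision file schema to internal fractions."""
    arms = {}
    for arm_id, block in _require(doc, "efficacy", "document").items():
        doses = {}
        for dose, row in _require(block, "doses", f"efficacy.{arm_id}").items():
            doses[dose] = {
                field: _require(row, field, f"efficacy.{arm_id}.doses.{dose}") / _PCT
                for field in _EFFICACY_FIELDS
            }
        arms[arm_id] = {
            "arm_id": arm_id,
            "start_dose": _require(block, "start_dose", f"efficacy.{arm_id}"),
            "high_dose": block.get("high_dose"),
            "doses": doses,
        }

    persistence = {
        arm_id: {"remaining": {int(w): v / _PCT for w, v in curve.items()}}
        for arm_id, curve in _require(doc, "persistence", "document").items()
    }
    shared = {
        "remaining": {int(w): v / _PCT
                      for w, v in _require(doc, "shared_persistence", "document").items()}
    }
    titration = {
        arm_id: {k: v / _PCT for k, v in block.items()}
        for arm_id, block in _require(doc, "titration", "document").items()
    }

    resource = {}
    for status, row in _require(doc, "resource_use", "document").items():
        row = dict(row)
        row["frac_using_pads"] = _require(row, "frac_using_pads",
                                          f"resource_use.{status}") / _PCT
        resource[status] = row

    comorbidity = {}
    for status, row in _require(doc, "comorbidity", "document").items():
        row = dict(row)
        for field in _COMORBIDITY_PCT_FIELDS:
            row[field] = _require(row, field, f"comorbidity.{status}") / _PCT
        comorbidity[status] = row
    decrements = dict(_require(doc, "utility_decrements", "document"))
    decrements = {k: (None if v is None else v / _PCT) for k, v in decrements.items()}

    def by_sex(block):
        if block is None:
            return None
        return {
            "frac_female": _require(block, "frac_female", "by-sex block") / _PCT,
            "controlled": block["controlled"],
            "uncontrolled": block["uncontrolled"],
        }

    dep_sex = by_sex(doc.get("depression_by_sex"))
    if dep_sex is not None:
        dep_sex["controlled"] = {k: v / _PCT for k, v in dep_sex["controlled"].items()}
        dep_sex["uncontrolled"] = {k: v / _PCT for k, v in dep_sex["uncontrolled"].items()}
    nh_sex = by_sex(doc.get("nursing_home_by_sex"))  # rates stay per-1000-py

    utilities = _require(doc, "utilities", "document")
    productivity = dict(_require(doc, "productivity", "document"))
    for field in _PRODUCTIVITY_PCT_FIELDS:
        productivity[field] = _require(productivity, field, "productivity") / _PCT

    settings = dict(doc.get("settings", {}))

    return {
        "arms": arms,
        "persistence": persistence,
        "shared_persistence": shared,
        "titration": titration,
        "unit_costs": _require(doc, "unit_costs", "document"),
        "resource_use": resource,
        "comorbidity": {
            **comorbidity,
            "depression_by_sex": dep_sex,
            "nursing_home_by_sex": nh_sex,
            "utility_decrements": decrements,
        },
        "utilities": {
            "u_continent": _require(utilities, "continent", "utilities"),
            "u_incontinent_on_rx": _require(utilities, "incontinent_on_rx", "utilities"),
            "u_untreated": _require(utilities, "untreated", "utilities"),
        },
        "productivity": productivity,
        **settings,
    }


def _internal_to_file_dict(params: ParameterSet) -> dict:
    """Inverse of :func:`_file_dict_to_internal` (lossless round-trip)."""

    def pct(value: float) -> float:
        # four decimals on the percent scale preserves every table value exactly
        return round(value * _PCT, 4)

    doc: dict = {"efficacy": {}}
    for arm_id, arm in params.arms.items():
        block: dict = {"start_dose": arm.start_dose}
        if arm.high_dose is not None:
            block["high_dose"] = arm.high_dose
        block["doses"] = {
            dose: {field: pct(getattr(eff, field)) for field in _EFFICACY_FIELDS}
            for dose, eff in arm.doses.items()
        }
        doc["efficacy"][arm_id] = block

    doc["persistence"] = {
        arm_id: {w: pct(v) for w, v in curve.remaining.items()}
        for arm_id, curve in params.persistence.items()
    }
    doc["shared_persistence"] = {
        w: pct(v) for w, v in params.shared_persistence.remaining.items()
    }
    doc["titration"] = {
        arm_id: {
            "frac_responders_titrate": pct(p.frac_responders_titrate),
            "frac_nonresponders_titrate": pct(p.frac_nonresponders_titrate),
        }
        for arm_id, p in params.titration.items()
    }
    doc["unit_costs"] = params.unit_costs.model_dump()
    doc["resource_use"] = {
        status: {**row.model_dump(), "frac_using_pads": pct(row.frac_using_pads)}
        for status, row in (
            ("controlled", params.resource_use.controlled),
            ("uncontrolled_on_rx", params.resource_use.uncontrolled_on_rx),
            ("untreated", params.resource_use.untreated),
        )
    }
    doc["comorbidity"] = {
        status: {
            **row.model_dump(),
            **{f: pct(getattr(row, f)) for f in _COMORBIDITY_PCT_FIELDS},
        }
        for status, row in (
            ("controlled", params.comorbidity.controlled),
            ("uncontrolled_on_rx", params.comorbidity.uncontrolled_on_rx),
            ("untreated", params.comorbidity.untreated),
        )
    }
    if params.comorbidity.depression_by_sex is not None:
        bs = params.comorbidity.depression_by_sex
        doc["depression_by_sex"] = {
            "frac_female": pct(bs.frac_female),
            "controlled": {"women": pct(bs.controlled.women), "men": pct(bs.controlled.men)},
            "uncontrolled": {"women": pct(bs.uncontrolled.women), "men": pct(bs.uncontrolled.men)},
        }
    if params.comorbidity.nursing_home_by_sex is not None:
        bs = params.comorbidity.nursing_home_by_sex
        doc["nursing_home_by_sex"] = {
            "frac_female": pct(bs.frac_female),
            "controlled": bs.controlled.model_dump(),
            "uncontrolled": bs.uncontrolled.model_dump(),
        }
    dec = params.comorbidity.utility_decrements
    doc["utility_decrements"] = {
        "fracture": pct(dec.fracture),
        "depression": pct(dec.depression),
        "nursing_home": None if dec.nursing_home is None else pct(dec.nursing_home),
    }
    doc["utilities"] = {
        "continent": params.utilities.u_continent,
        "incontinent_on_rx": params.utilities.u_incontinent_on_rx,
        "untreated": params.utilities.u_untreated,
    }
    prod = params.productivity.model_dump()
    for field in _PRODUCTIVITY_PCT_FIELDS:
        prod[field] = pct(prod[field])
    doc["productivity"] = prod
    doc["settings"] = {
        "horizon_weeks": params.horizon_weeks,
        "perspective": params.perspective,
        "decrements_enabled": params.decrements_enabled,
        "annualization_factor": params.annualization_factor,
    }
    return doc


def parameter_set_from_internal(internal: dict) -> ParameterSet:
    """Validate an internal-scale (fractions) dictionary into a ParameterSet,
    reporting type/range failures as :class:`ParameterValidationError`."""
    try:
        return ParameterSet.model_validate(internal)
    except ValidationError as exc:
        violations = [
            Violation(path=".".join(str(loc) for loc in err["loc"]), message=err["msg"])
            for err in exc.errors()
        ]
        raise ParameterValidationError(violations) from exc


def parameter_set_from_dict(doc: dict) -> ParameterSet:
    """Build and fully validate a ParameterSet from a file-schema dictionary."""
    params = parameter_set_from_internal(_file_dict_to_internal(doc))
    report = validate(params)
    if report:
        raise ParameterValidationError(report)
    return params


def load_parameter_set(source: str | Path) -> ParameterSet:
    """Load and validate a YAML parameter file.

    Raises :class:`ConfigurationError` for missing keys and
    :class:`ParameterValidationError` (listing every violation with its
    parameter path) for out-of-range or mutually inconsistent values.
    """
    path = Path(source)
    if not path.exists():
        raise ConfigurationError(f"parameter file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"parameter file {path} is not a mapping")
    return parameter_set_from_dict(doc)


def save_parameter_set(params: ParameterSet, target: str | Path) -> None:
    """Write ``params`` back to the percent-precision file schema."""
    with open(target, "w") as fh:
        yaml.safe_dump(_internal_to_file_dict(params), fh, sort_keys=False)


def fixture_hash(params: ParameterSet) -> str:
    """Stable content hash of a parameter set, for report provenance."""
    import hashlib
    import json

    payload = json.dumps(params.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
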