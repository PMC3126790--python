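"""Per-arm euro cost accrual over the model horizon.

Components: drug acquisition, incontinence pads, physician visits and
laboratory tests, constipation management, status-conditional comorbidity
costs (fracture, skin infection, UTI, depression, nursing home) and the
productivity effect relative to an all-untreated cohort (a non-positive
"relative productivity gain").  The payer perspective excludes the
productivity component; the societal perspective includes it.

Accrual conventions (all logged in the run report):

* occupancy weighting uses the same end-of-period convention as the QALY
  accrual: each period is valued at the occupancy of its closing checkpoint;
* 6-month comorbidity probabilities and per-person event counts are
  annualized with a configurable factor (default x2);
* treatment days run on a 364-day (52 x 7) year, pad use on a 365-day year,
  visit/laboratory rates on 12 months per year;
* nursing-home cost is the admission rate per patient-year times the cost
  per admitted patient-year; depression the annual probability times the
  annual per-patient cost;
* during the first period the first 4 weeks of drug are priced at the start
  dose and the remaining weeks at the post-titration dose mix; later periods
  use the survivors' dose mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .engine import OccupancyTrajectory, dose_mix
from .parameters import ParameterSet, StatusComorbidity, StatusResourceUse

DIRECT_COMPONENTS = ("drug", "pads", "visits_labs", "constipation",
                     "fracture", "skin", "uti", "depression", "nursing_home")

_STATE_TO_STATUS = {
    "continent": "controlled",
    "incontinent_on_rx": "uncontrolled_on_rx",
    "untreated": "untreated",
}

TREATMENT_DAYS_PER_YEAR = 364.0
DAYS_PER_YEAR = 365.0
MONTHS_PER_YEAR = 12.0
WEEKS_PER_YEAR = 52.0


@dataclass(frozen=True)
class CostBreakdown:
    """Per-component euro accrual for one arm under a stated perspective."""

    arm_id: str
    perspective: str
    drug: float
    pads: float
    visits_labs: float
    constipation: float
    fracture: float
    skin: float
    uti: float
    depression: float
    nursing_home: float
    productivity: float
    total_payer: float = field(init=False)
    total_societal: float = field(init=False)

    def __post_init__(self):
        direct = sum(getattr(self, c) for c in DIRECT_COMPONENTS)
        object.__setattr__(self, "total_payer", direct)
        object.__setattr__(self, "total_societal", direct + self.productivity)

    @property
    def total(self) -> float:
        return self.total_societal if self.perspective == "societal" else self.total_payer

    def as_dict(self) -> dict[str, float]:
        out = {c: getattr(self, c) for c in DIRECT_COMPONENTS}
        out["productivity"] = self.productivity
        out["total_payer"] = self.total_payer
        out["total_societal"] = self.total_societal
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.arm_id, name, value) for name, value in self.as_dict().items()]
        return pd.DataFrame(rows, columns=["arm", "component", "eur"])


def _periods(params: ParameterSet) -> tuple[tuple[int, float], ...]:
    """(closing checkpoint week, year fraction) accrual schedule."""
    from .qaly import period_weights

    return period_weights(params.horizon_weeks).periods


def _state_occupancies(traj: OccupancyTrajectory, week: int) -> dict[str, float]:
    occ = traj.at(week)
    return {"continent": occ.continent,
            "incontinent_on_rx": occ.incontinent,
            "untreated": occ.untreated}


def drug_cost(traj: OccupancyTrajectory, params: ParameterSet) -> float:
    """Drug acquisition cost over the horizon.

    Days 0-28 are priced at the start dose, days 28-84 at the post-titration
    mix, and any later period at its survivors' dose mix, each weighted by
    the on-treatment occupancy at the closing checkpoint of the period.
    """
    arm = params.arms[traj.arm_id]
    prices = params.unit_costs.drug_per_day[traj.arm_id]

    def mix_price(week: int) -> float:
        occ = traj.at(week)
        if occ.on_treatment <= 0.0:
            return 0.0
        return sum(share * prices[dose] for dose, share in dose_mix(traj, week).items())

    total = 0.0
    for week, year_frac in _periods(params):
        days = TREATMENT_DAYS_PER_YEAR * year_frac
        on_rx = traj.at(week).on_treatment
        if week == 12:
            start_days = TREATMENT_DAYS_PER_YEAR * 4 / 52
            total += on_rx * (start_days * prices[arm.start_dose]
                              + (days - start_days) * mix_price(week))
        else:
            total += on_rx * days * mix_price(week)
    return total


def _pads_annual(use: StatusResourceUse, params: ParameterSet) -> float:
    return use.frac_using_pads * use.pads_per_day * params.unit_costs.pad * DAYS_PER_YEAR


def _visits_annual(use: StatusResourceUse, params: ParameterSet) -> float:
    uc = params.unit_costs
    monthly = (use.gp_visits_per_month * uc.gp_visit
               + use.specialist_visits_per_month * uc.specialist_visit
               + use.lab_tests_per_month * uc.lab_test)
    return monthly * MONTHS_PER_YEAR


def resource_cost(traj: OccupancyTrajectory, params: ParameterSet) -> tuple[float, float]:
    """(pads, visits + laboratory) euro accruals over the horizon."""
    pads = visits = 0.0
    for week, year_frac in _periods(params):
        for state, occ in _state_occupancies(traj, week).items():
            use = getattr(params.resource_use, _STATE_TO_STATUS[state])
            pads += year_frac * occ * _pads_annual(use, params)
            visits += year_frac * occ * _visits_annual(use, params)
    return pads, visits


def _comorbidity_annual(com: StatusComorbidity, params: ParameterSet) -> dict[str, float]:
    uc, k = params.unit_costs, params.annualization_factor
    return {
        "fracture": com.fracture_prob_6mo * k * uc.fracture_event,
        "skin": com.skin_events_per_person * k * uc.skin_infection_episode,
        "uti": com.uti_events_per_person * k * uc.uti_episode,
        "depression": com.depression_prob_annual * uc.depression_per_patient_year,
        "nursing_home": (com.nursing_home_admissions_per_1000py / 1000.0) * uc.nursing_home,
    }


def comorbidity_cost(traj: OccupancyTrajectory, params: ParameterSet) -> dict[str, float]:
    """Euro accrual per comorbid condition over the horizon."""
    totals = {"fracture": 0.0, "skin": 0.0, "uti": 0.0,
              "depression": 0.0, "nursing_home": 0.0}
    for week, year_frac in _periods(params):
        for state, occ in _state_occupancies(traj, week).items():
            annual = _comorbidity_annual(
                params.comorbidity.for_status(_STATE_TO_STATUS[state]), params)
            for condition, rate in annual.items():
                totals[condition] += year_frac * occ * rate
    return totals


def constipation_cost(traj: OccupancyTrajectory, params: ParameterSet) -> float:
    """Constipation management: EUR/day over on-treatment days, dose-specific rate."""
    arm = params.arms[traj.arm_id]
    total = 0.0
    for week, year_frac in _periods(params):
        occ = traj.at(week)
        if occ.on_treatment <= 0.0:
            continue
        rate = sum(share * arm.doses[dose].constipation_rate
                   for dose, share in dose_mix(traj, week).items())
        total += (occ.on_treatment * rate
                  * params.unit_costs.constipation_per_day
                  * TREATMENT_DAYS_PER_YEAR * year_frac)
    return total


def productivity_cost(traj: OccupancyTrajectory, params: ParameterSet) -> float:
    """Productivity effect relative to an all-untreated cohort (<= 0 euros).

    Two channels: employed patients restored to continence no longer reduce
    their worked hours, and treated patients whose baseline nocturia
    resolves no longer lose on-the-job productivity.  Both are valued at the
    average wage and returned as negative euros (relative gains).
    """
    prod = params.productivity
    arm = params.arms[traj.arm_id]
    wage_hours = prod.wage_per_hour * prod.hours_per_week * prod.frac_employed
    gain = 0.0
    for week, year_frac in _periods(params):
        occ = traj.at(week)
        weeks = WEEKS_PER_YEAR * year_frac
        gain += (occ.continent * prod.effective_hours_reduction
                 * wage_hours * weeks)
        if occ.on_treatment > 0.0:
            resolution = sum(share * arm.doses[dose].nocturia_resolution_w12
                             for dose, share in dose_mix(traj, week).items())
            gain += (occ.on_treatment * prod.baseline_nocturia_prevalence
                     * resolution * prod.nocturia_impairment
                     * wage_hours * weeks)
    return -gain


def total_cost(traj: OccupancyTrajectory, params: ParameterSet,
               perspective: str | None = None) -> CostBreakdown:
    """Full per-arm cost breakdown under the given perspective."""
    perspective = perspective or params.perspective
    if perspective not in ("societal", "payer"):
        raise ValueError(f"unknown perspective '{perspective}'")
    pads, visits = resource_cost(traj, params)
    comorbid = comorbidity_cost(traj, params)
    return CostBreakdown(
        arm_id=traj.arm_id,
        perspective=perspective,
        drug=drug_cost(traj, params),
        pads=pads,
        visits_labs=visits,
        constipation=constipation_cost(traj, params),
        fracture=comorbid["fracture"],
        skin=comorbid["skin"],
        uti=comorbid["uti"],
        depression=comorbid["depression"],
        nursing_home=comorbid["nursing_home"],
        productivity=productivity_cost(traj, params),
    )
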