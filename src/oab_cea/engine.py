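"""Cohort propagation through the decision tree.

A unit cohort starts on the arm's initial dose.  At week 4 the cohort is
split by week-8-proxy response status and by the titration policy into up
to four branches (responder/non-responder x stay/titrate), each carrying a
dose label.  At week 12 each branch responds with the branch-appropriate
conditional probability; non-responders discontinue.  Week-12 responders
are carried forward unchanged (last observation carried forward) and only
leave therapy through the shared persistence curve, which removes patients
proportionally from the continent-on-treatment branches into the untreated
state at weeks 24 and 52.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .parameters import ArmEfficacy, ConfigurationError, ParameterSet, TitrationPolicy

CHECKPOINTS = (8, 12, 24, 52)


@dataclass(frozen=True)
class Branch:
    dose: str
    responder_w8: bool
    fraction: float


@dataclass(frozen=True)
class BranchSplit:
    """Cohort fractions after the week-4 titration decision."""

    responder_stay: Branch
    responder_titrate: Branch
    nonresponder_stay: Branch
    nonresponder_titrate: Branch

    @property
    def branches(self) -> tuple[Branch, ...]:
        return (self.responder_stay, self.responder_titrate,
                self.nonresponder_stay, self.nonresponder_titrate)

    @property
    def total(self) -> float:
        return sum(b.fraction for b in self.branches)

    def dose_mix(self) -> dict[str, float]:
        mix: dict[str, float] = {}
        for b in self.branches:
            mix[b.dose] = mix.get(b.dose, 0.0) + b.fraction
        return mix


def apply_titration(response_w8proxy: float, policy: TitrationPolicy,
                    start_dose: str, high_dose: str | None) -> BranchSplit:
    """Split the cohort at week 4 using week-8 trial data as proxy.

    Responder branches sum to the week-8-proxy response probability and
    non-responder branches to its complement.  For single-dose arms the
    titrate branches are empty and carry the start dose label.
    """
    if not 0.0 <= response_w8proxy <= 1.0:
        raise ValueError("response probability outside [0, 1]")
    t_resp = policy.frac_responders_titrate if high_dose else 0.0
    t_nonresp = policy.frac_nonresponders_titrate if high_dose else 0.0
    up = high_dose if high_dose else start_dose
    r, n = response_w8proxy, 1.0 - response_w8proxy
    return BranchSplit(
        responder_stay=Branch(start_dose, True, r * (1.0 - t_resp)),
        responder_titrate=Branch(up, True, r * t_resp),
        nonresponder_stay=Branch(start_dose, False, n * (1.0 - t_nonresp)),
        nonresponder_titrate=Branch(up, False, n * t_nonresp),
    )


def response_at_w12(split: BranchSplit, eff: ArmEfficacy) -> float:
    """Pre-attrition week-12 response probability of the whole cohort."""
    total = 0.0
    for branch in split.branches:
        if branch.fraction == 0.0:
            continue
        dose = eff.doses.get(branch.dose)
        if dose is None:
            raise ConfigurationError(
                f"no conditional response data for dose '{branch.dose}'"
            )
        cond = (dose.cond_w12_given_w8resp if branch.responder_w8
                else dose.cond_w12_given_w8nonresp)
        total += branch.fraction * cond
    return total


@dataclass(frozen=True)
class Occupancy:
    """State fractions at one checkpoint (sum to 1)."""

    continent_on_rx: dict[str, float]   # by dose
    incontinent_on_rx: dict[str, float]  # by dose
    untreated: float

    @property
    def continent(self) -> float:
        return sum(self.continent_on_rx.values())

    @property
    def incontinent(self) -> float:
        return sum(self.incontinent_on_rx.values())

    @property
    def on_treatment(self) -> float:
        return self.continent + self.incontinent

    @property
    def total(self) -> float:
        return self.on_treatment + self.untreated


@dataclass(frozen=True)
class OccupancyTrajectory:
    arm_id: str
    checkpoints: dict[int, Occupancy]
    response_w12: float = field(default=0.0)

    def at(self, week: int) -> Occupancy:
        try:
            return self.checkpoints[week]
        except KeyError:
            raise KeyError(
                f"week {week} is not a checkpoint of this trajectory "
                f"(have {sorted(self.checkpoints)})"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per week/state/dose."""
        rows = []
        for week in sorted(self.checkpoints):
            occ = self.checkpoints[week]
            for dose, frac in occ.continent_on_rx.items():
                rows.append((week, "continent_on_rx", dose, frac))
            for dose, frac in occ.incontinent_on_rx.items():
                rows.append((week, "incontinent_on_rx", dose, frac))
            rows.append((week, "untreated", "", occ.untreated))
        return pd.DataFrame(rows, columns=["week", "state", "dose", "fraction"])


def run_cohort(arm_id: str, params: ParameterSet) -> OccupancyTrajectory:
    """Propagate a unit cohort of ``arm_id`` starters to week 52."""
    if arm_id not in params.arms:
        raise ConfigurationError(f"unknown arm '{arm_id}'")
    arm = params.arms[arm_id]
    policy = params.titration[arm_id]
    for week in CHECKPOINTS:
        params.persistence_at(arm_id, week)  # raises if a checkpoint is missing

    r8 = arm.doses[arm.start_dose].response_w8
    split = apply_titration(r8, policy, arm.start_dose, arm.high_dose)
    raw_r12 = response_at_w12(split, arm)
    # uniform week-12 response rescaling (sensitivity knob), capped at 1;
    # the dose composition of responders is preserved up to per-dose caps
    response_scale = min(params.w12_response_scale,
                         1.0 / raw_r12 if raw_r12 > 0 else 1.0)

    checkpoints: dict[int, Occupancy] = {}

    # week 8: titration has happened (week 4), status is week-8-proxy response;
    # arm-specific early persistence applies
    p8 = params.persistence_at(arm_id, 8)
    cont8: dict[str, float] = {}
    incont8: dict[str, float] = {}
    for b in split.branches:
        target = cont8 if b.responder_w8 else incont8
        target[b.dose] = target.get(b.dose, 0.0) + b.fraction * p8
    checkpoints[8] = Occupancy(cont8, incont8, 1.0 - p8)

    # week 12: branch-conditional response, shared persistence; non-responders
    # are still on treatment at the assessment itself
    p12 = params.persistence_at(arm_id, 12)
    resp_frac: dict[str, float] = {}   # responders at 12 by dose, pre-persistence
    dose_total: dict[str, float] = {}  # cohort share of each dose
    for b in split.branches:
        if b.fraction == 0.0:
            continue
        dose = arm.doses[b.dose]
        cond = (dose.cond_w12_given_w8resp if b.responder_w8
                else dose.cond_w12_given_w8nonresp)
        resp_frac[b.dose] = resp_frac.get(b.dose, 0.0) + b.fraction * cond
        dose_total[b.dose] = dose_total.get(b.dose, 0.0) + b.fraction
    cont12 = {dose: min(frac * response_scale, dose_total[dose]) * p12
              for dose, frac in resp_frac.items()}
    incont12 = {dose: dose_total[dose] * p12 - cont12[dose] for dose in dose_total}
    r12 = sum(cont12.values()) / p12 if p12 > 0 else 0.0
    checkpoints[12] = Occupancy(cont12, incont12, 1.0 - p12)

    # weeks 24/52: only week-12 responders remain on therapy; persistence
    # attrition removes them proportionally across doses into untreated
    for week in (24, 52):
        p = params.persistence_at(arm_id, week)
        scale = p / p12 if p12 > 0 else 0.0
        cont = {dose: frac * scale for dose, frac in cont12.items()}
        checkpoints[week] = Occupancy(cont, {}, 1.0 - sum(cont.values()))

    return OccupancyTrajectory(arm_id=arm_id, checkpoints=checkpoints,
                               response_w12=r12)


def continent_fraction(traj: OccupancyTrajectory, week: int) -> float:
    """Total continent-on-treatment fraction at a checkpoint week."""
    return traj.at(week).continent


def dose_mix(traj: OccupancyTrajectory, week: int) -> dict[str, float]:
    """Dose fractions among on-treatment patients at a checkpoint week.

    Raises :class:`ZeroDivisionError` when nobody is on treatment, in which
    case a dose mix is undefined.
    """
    occ = traj.at(week)
    on_rx = occ.on_treatment
    if on_rx <= 0.0:
        raise ZeroDivisionError(f"no patients on treatment at week {week}")
    mix: dict[str, float] = {}
    for source in (occ.continent_on_rx, occ.incontinent_on_rx):
        for dose, frac in source.items():
            mix[dose] = mix.get(dose, 0.0) + frac / on_rx
    return mix
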