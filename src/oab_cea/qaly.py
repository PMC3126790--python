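"""QALY accrual from an occupancy trajectory.

Effectiveness is the QALY gain over the all-untreated baseline: each
accrual period is valued at the occupancy of its closing checkpoint
(end-of-period convention) times the state-utility increment over the
untreated baseline utility.  Periods are (0-12], (12-24] and (24-52]
weeks for the 52-week horizon and a single (0-12] period for the 12-week
horizon.  No discounting is applied at a one-year horizon.

Comorbidity utility decrements (fracture, depression, nursing home) can
optionally be folded into the state utilities; they default off because
the published base-case gains are reproduced without them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import OccupancyTrajectory
from .parameters import ComorbidityProfile, ParameterSet, UtilitySet

STATES = ("continent", "incontinent_on_rx", "untreated")

_STATE_TO_STATUS = {
    "continent": "controlled",
    "incontinent_on_rx": "uncontrolled_on_rx",
    "untreated": "untreated",
}


@dataclass(frozen=True)
class PeriodWeights:
    """Accrual periods as (closing checkpoint week, year-fraction weight)."""

    periods: tuple[tuple[int, float], ...]

    @property
    def horizon_years(self) -> float:
        return sum(weight for _, weight in self.periods)


def period_weights(horizon_weeks: int) -> PeriodWeights:
    if horizon_weeks == 52:
        return PeriodWeights(((12, 12 / 52), (24, 12 / 52), (52, 28 / 52)))
    if horizon_weeks == 12:
        return PeriodWeights(((12, 12 / 52),))
    raise ValueError(f"unsupported horizon: {horizon_weeks} weeks")


def effective_state_utilities(utilities: UtilitySet,
                              comorbidity: ComorbidityProfile,
                              decrements_enabled: bool,
                              annualization_factor: float = 2.0) -> dict[str, float]:
    """State utilities, optionally reduced by comorbidity decrements.

    With decrements enabled, each state's utility is multiplied by
    ``1 - sum(annual probability x decrement fraction)`` over fracture,
    depression and nursing-home admission, using that state's incidence
    rates (6-month fracture probabilities are annualized).
    """
    if not decrements_enabled:
        return {state: utilities.for_state(state) for state in STATES}
    dec = comorbidity.utility_decrements
    out: dict[str, float] = {}
    for state in STATES:
        com = comorbidity.for_status(_STATE_TO_STATUS[state])
        burden = (
            com.fracture_prob_6mo * annualization_factor * dec.fracture
            + com.depression_prob_annual * dec.depression
            + com.nursing_home_admissions_per_1000py / 1000.0 * dec.nursing_home_or_zero
        )
        value = utilities.for_state(state) * (1.0 - burden)
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"effective utility for state '{state}' outside [0, 1]")
        out[state] = value
    return out


def qaly_gain(traj: OccupancyTrajectory, state_utilities: dict[str, float],
              weights: PeriodWeights) -> float:
    """QALY gain versus an always-untreated cohort over the horizon.

    The untreated state contributes zero by construction, since its
    utility increment over the baseline is zero.
    """
    u_base = state_utilities["untreated"]
    gain = 0.0
    for week, weight in weights.periods:
        occ = traj.at(week)
        gain += weight * (
            occ.continent * (state_utilities["continent"] - u_base)
            + occ.incontinent * (state_utilities["incontinent_on_rx"] - u_base)
        )
    return gain


def qaly_absolute(traj: OccupancyTrajectory, state_utilities: dict[str, float],
                  weights: PeriodWeights) -> float:
    """Absolute QALY accrual: the gain plus the untreated baseline accrual."""
    return (qaly_gain(traj, state_utilities, weights)
            + weights.horizon_years * state_utilities["untreated"])


def arm_qaly_gain(arm_id: str, params: ParameterSet,
                  traj: OccupancyTrajectory | None = None) -> float:
    """Convenience wrapper: run (or reuse) the trajectory and accrue the gain."""
    from .engine import run_cohort

    if traj is None:
        traj = run_cohort(arm_id, params)
    utils = effective_state_utilities(
        params.utilities, params.comorbidity, params.decrements_enabled,
        params.annualization_factor,
    )
    return qaly_gain(traj, utils, period_weights(params.horizon_weeks))
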