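"""Run-report assembly: base-case outcome table and tornado table as
machine-readable CSV/JSON, with the convention ledger and provenance.

Report regeneration from the same inputs is bit-identical: everything is
deterministic and the provenance block records the parameter-set hash.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cea import CEAResult, compare
from .costs import CostBreakdown, total_cost
from .engine import OccupancyTrajectory, run_cohort
from .parameters import ParameterSet, fixture_hash
from .qaly import arm_qaly_gain
from .sensitivity import COMPARATOR_ARMS, REFERENCE_ARM, TornadoRow, tornado_frame

DEFAULT_ARMS = (REFERENCE_ARM,) + COMPARATOR_ARMS


def conventions(params: ParameterSet) -> dict:
    """Every accrual-convention toggle in effect, for auditability."""
    return {
        "horizon_weeks": params.horizon_weeks,
        "perspective": params.perspective,
        "occupancy_convention": "end-of-period",
        "period_schedule_weeks": [12, 24, 52] if params.horizon_weeks == 52 else [12],
        "decrements_enabled": params.decrements_enabled,
        "annualization_factor": params.annualization_factor,
        "hours_reduction_mode": params.productivity.hours_reduction_mode,
        "effective_hours_reduction": params.productivity.effective_hours_reduction,
        "treatment_days_per_year": 364,
        "days_per_year": 365,
        "nursing_home_utility_decrement":
            params.comorbidity.utility_decrements.nursing_home,
    }


@dataclass(frozen=True)
class ArmOutcome:
    arm_id: str
    trajectory: OccupancyTrajectory
    qaly_gain: float
    costs: CostBreakdown

    @property
    def continent_w12(self) -> float:
        return self.trajectory.at(12).continent

    @property
    def continent_w52(self) -> float:
        return self.trajectory.at(52).continent


@dataclass(frozen=True)
class RunReport:
    outcomes: dict[str, ArmOutcome]
    cea: dict[str, CEAResult]           # comparator -> result vs reference
    conventions: dict
    provenance: dict

    def outcome_frame(self) -> pd.DataFrame:
        rows = []
        for arm_id, out in self.outcomes.items():
            row = {
                "arm": arm_id,
                "continent_w12_pct": round(100 * out.continent_w12, 1),
                "continent_w52_pct": round(100 * out.continent_w52, 1),
                "qaly_gain": round(out.qaly_gain, 5),
                **{k: round(v, 2) for k, v in out.costs.as_dict().items()},
            }
            rows.append(row)
        return pd.DataFrame(rows)

    def cea_frame(self) -> pd.DataFrame:
        return pd.DataFrame([res.as_dict() for res in self.cea.values()])

    def as_dict(self) -> dict:
        return {
            "outcomes": self.outcome_frame().to_dict(orient="records"),
            "cea": [res.as_dict() for res in self.cea.values()],
            "conventions": self.conventions,
            "provenance": self.provenance,
        }

    def write(self, out_prefix: str | Path) -> list[Path]:
        """Write <prefix>_outcomes.csv, <prefix>_cea.csv and <prefix>.json."""
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = [prefix.with_name(prefix.name + "_outcomes.csv"),
                 prefix.with_name(prefix.name + "_cea.csv"),
                 prefix.with_name(prefix.name + ".json")]
        self.outcome_frame().to_csv(paths[0], index=False)
        self.cea_frame().to_csv(paths[1], index=False)
        paths[2].write_text(json.dumps(self.as_dict(), indent=2))
        return paths


def build_run_report(params: ParameterSet,
                     arms: tuple[str, ...] = DEFAULT_ARMS,
                     reference: str = REFERENCE_ARM) -> RunReport:
    """Run every arm through the pipeline and assemble the report."""
    outcomes: dict[str, ArmOutcome] = {}
    for arm_id in arms:
        traj = run_cohort(arm_id, params)
        outcomes[arm_id] = ArmOutcome(
            arm_id=arm_id,
            trajectory=traj,
            qaly_gain=arm_qaly_gain(arm_id, params, traj),
            costs=total_cost(traj, params),
        )
    ref = outcomes[reference]
    cea = {
        arm_id: compare((ref.costs.total, ref.qaly_gain),
                        (out.costs.total, out.qaly_gain),
                        ref_arm=reference, comp_arm=arm_id)
        for arm_id, out in outcomes.items() if arm_id != reference
    }
    return RunReport(
        outcomes=outcomes,
        cea=cea,
        conventions=conventions(params),
        provenance={"parameter_hash": fixture_hash(params)},
    )


def write_tornado(rows: list[TornadoRow], out_prefix: str | Path,
                  params: ParameterSet) -> list[Path]:
    """Write the tornado table as CSV and JSON next to the run report."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    frame = tornado_frame(rows)
    csv_path = prefix.with_name(prefix.name + "_tornado.csv")
    json_path = prefix.with_name(prefix.name + "_tornado.json")
    frame.to_csv(csv_path, index=False)
    payload = {
        "rows": [
            {"scenario": row.scenario,
             "results": {comp: res.as_dict() for comp, res in row.results.items()}}
            for row in rows
        ],
        "conventions": conventions(params),
        "provenance": {"parameter_hash": fixture_hash(params)},
    }
    json_path.write_text(json.dumps(payload, indent=2))
    return [csv_path, json_path]
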