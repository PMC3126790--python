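# oab-cea

A decision-tree cohort cost-effectiveness model for antimuscarinic treatment
of overactive bladder (OAB) with urgency incontinence, comparing
**fesoterodine** (4 mg, titratable to 8 mg) against **extended-release
tolterodine** (4 mg) and **solifenacin** (5 mg, titratable to 10 mg) over a
52-week horizon from the societal or the health-system (payer) perspective,
with Spanish 2010 cost inputs.

It is written for health economists and HTA analysts who want a validated,
scriptable re-implementation of this class of spreadsheet model: every input
is a typed, range-checked parameter, every accrual convention is explicit
and logged, and the cohort arithmetic is cross-checked against an
individual-level microsimulation.

## The model

A unit cohort starts on the arm's initial dose. At week 4, using week-8
trial data as a proxy, the cohort splits by response status
(*responder* = continent, fewer than one urge-incontinence episode per
24 h); for titratable arms 50% of responders and 50% of non-responders
escalate to the high dose. At week 12 each branch responds with the
branch-appropriate conditional probability P(responder at 12 | status at 8);
non-responders discontinue. Responders keep their status to week 52 (last
observation carried forward) and leave therapy only through the shared
persistence curve. For each checkpoint occupancy vector **x**(t) over the
states {continent on treatment, incontinent on treatment, untreated}:

* **QALY gain** = Σ periods w·Σ states x(state)·(u(state) − u(untreated)), with
  period weights 12/52, 12/52, 28/52 years valued at the occupancy of each
  period's closing checkpoint, utilities u = (0.9569, 0.9412, 0.9332),
  undiscounted;
* **cost** = drug + pads + visits/labs + constipation + status-conditional
  comorbidity costs (fracture, skin infection, UTI, depression, nursing
  home) + productivity effect (≤ 0, relative to no treatment; societal
  perspective only);
* **ICER** = Δcost/ΔQALY between two arms, with dominance ("cost-saving")
  when the reference is cheaper and more effective, judged against a
  €30,000/QALY willingness-to-pay threshold.

A univariate sensitivity module re-runs the pipeline under ±25%
perturbations of every parameter group plus horizon (52→12 weeks) and
perspective switches, producing a tornado table.

## Worked example

```bash
oab-cea run --paper --out report
```

prints the base case (52 weeks, societal perspective) and writes
`report_outcomes.csv`, `report_cea.csv` and `report.json`:

```text
         arm  continent_w12_pct  continent_w52_pct  qaly_gain   drug  ...  total_societal
fesoterodine               50.6               33.1    0.01015 382.29  ...         1851.16
 tolterodine               40.6               26.5    0.00847 268.54  ...         2053.59
 solifenacin               47.2               30.9    0.00958 359.14  ...         1881.89
   reference  comparator  delta_cost  delta_qaly icer       label quadrant  threshold_pass
fesoterodine tolterodine -202.429398    0.001677 None cost-saving       SE            True
fesoterodine solifenacin  -30.727953    0.000569 None cost-saving       SE            True
```

Reading: half of fesoterodine starters (50.6%) are continent at week 12 and
33.1% are still continent on therapy at week 52, more than on either
comparator. The fesoterodine arm accrues 0.01015 QALYs more than an
untreated cohort over the year and costs €1,851 per patient from the
societal perspective — less than both comparators while gaining more QALYs,
so it dominates ("cost-saving", south-east quadrant) and no ratio is
reported. Column-by-column cost components (pads, comorbidities,
productivity, ...) are in the CSV/JSON outputs, along with the convention
ledger that records every accrual toggle in effect.

The sensitivity grid, horizon and perspective switches:

```bash
oab-cea sensitivity --paper --out report      # tornado table (CSV + JSON)
oab-cea run --paper --horizon 12 --perspective payer --out short
oab-cea init --paper --out myparams.yaml      # editable parameter file
oab-cea validate --config myparams.yaml
```

Everything is also available as a library:

```python
from oab_cea import paper_basecase, run_cohort, total_cost
params = paper_basecase()
traj = run_cohort("fesoterodine", params)
print(traj.at(12).continent, total_cost(traj, params).total_societal)
```

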