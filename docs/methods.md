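# Methods

## Model structure and assumptions

The model is a deterministic decision-tree cohort simulation of one year of
antimuscarinic therapy for OAB with urgency incontinence. A unit cohort per
arm moves through five checkpoint weeks {2, 8, 12, 24, 52} over three
states: continent on treatment, incontinent on treatment, untreated.

Key structural assumptions, all fixed by the published study design:

* **Week-4 titration with week-8 proxy data.** The dose-escalation decision
  happens at week 4, but trial endpoints exist only at weeks 2, 8 and 12,
  so week-8 response is used as the proxy for the decision. The engine has
  no separate week-4 state; the week-8 checkpoint already reflects the
  post-titration dose mix. Before week 4 everyone is on the start dose.
* **Titration policy.** 50% of week-8-proxy responders and 50% of
  non-responders on fesoterodine 4 mg and solifenacin 5 mg escalate to the
  high dose; tolterodine is single-dose, so its cohort has two branches and
  both probabilities are structurally zero.
* **Week-12 responder gate.** Each branch responds with the conditional
  probability appropriate to its week-8 status and branch dose
  (P(12|8-resp), P(12|8-nonresp), both taken directly from the source
  table). Week-12 non-responders discontinue; no further titration or dose
  lowering occurs.
* **Last observation carried forward.** Week-12 responders keep their
  status to week 52. Attrition after week 12 follows the shared (placebo)
  persistence curve, removing patients proportionally from the
  continent-on-treatment branches into the untreated state; after week 12
  everyone still on treatment is a responder.
* **Persistence.** Arm-specific persistence applies through week 8
  (92.67% / 95.76% / 94.06%); from week 12 the shared placebo curve
  (90.64% / 79.32% / 59.27% at weeks 12/24/52) applies to every arm.
  Continence outputs depend only on the shared curve, which is what
  reproduces the published continence table; the arm-specific early values
  are carried in the trajectory's week-8 checkpoint.
* The printed week-2 response values are loaded and validated but unused:
  no output depends on them.

The week-12-given-week-8 conditional column equals the ratio of the two
marginals in every printed row, and cannot simultaneously be consistent
with the week-12-given-non-response column under the law of total
probability. The engine therefore uses both conditional columns exactly as
printed (this is what reproduces the published occupancy), and the
`conditional_from_marginals` derivation is validated against the
responder column only, with a ±0.005 consistency band that absorbs the
source's independent rounding of each cell.

## Effectiveness

QALY gain is accrued against the all-untreated baseline utility (0.9332)
over periods (0–12], (12–24], (24–52] weeks with year-fraction weights
12/52, 12/52, 28/52, each valued at the occupancy of its **closing
checkpoint**. During the first period the week-12 non-responders are still
on treatment (incontinent-on-treatment = persistence(12) − continent(12));
later periods contain responders only. This end-of-period convention is the
unique simple accrual rule that reproduces all three published base-case
gains to ≈1×10⁻⁵, and the cost accrual uses the same rule for consistency.
No discounting is applied at a one-year horizon.

Comorbidity utility decrements (fracture −4%, depression −48%, nursing home
printed without a value, default 0 and configurable) are implemented as
multiplicative reductions of the state utilities by
1 − Σ annual-probability × decrement, but **default off**: the published
QALY gains are reproduced almost exactly without them, so whether and how
they entered the published base case is indeterminate. Both modes are
supported (`decrements_enabled`); enabling them lowers all three gains
roughly proportionally and does not change any dominance conclusion.

## Cost accrual conventions

All conventions are logged in the run report (`conventions` block) so two
runs are diff-comparable.

* **Occupancy weighting**: end-of-period, identical to the QALY rule.
  Period lengths 84/84/196 days (a single 84-day period at the 12-week
  horizon).
* **Time bases**: treatment days on a 364-day (52×7) year — the first 28
  days of each run priced at the start dose, the remainder at the
  post-titration / survivor dose mix; pads on a 365-day year; visit and
  laboratory rates on 12 months/year.
* **Annualization ×2**: the source lists 6-month windows for fracture
  probabilities and skin/UTI expected event counts under a "rate per year"
  heading; the package doubles the 6-month quantities. The factor is a
  flagged, configurable convention (`annualization_factor`).
* **Nursing home**: admission rate per 1000 patient-years × cost per
  admitted patient-year. **Depression**: annual probability × annual
  per-patient cost, using the printed "overall" rates (the sex-specific
  rows and the 80.87% female share are stored for sensitivity use).
* **Untreated patients** accrue the untreated column's utilization and
  comorbidity rates for the remainder of the horizon.
* **Constipation**: €/day × dose-specific constipation rate over
  on-treatment days.

### Productivity and the hours-reduction mode

Productivity is computed relative to an all-untreated cohort and enters the
societal perspective only, as a non-positive "relative gain". Two channels:

* avoided hours reduction: continent occupancy × hours-reduction fraction ×
  40 h/week × €13.51/h × 59.83% employed;
* avoided nocturia impairment: on-treatment occupancy × 48.58% baseline
  nocturia prevalence × dose-mix-weighted week-12 nocturia resolution ×
  9.2% work impairment × the same wage base.

The source prints a uniform 21.1% hours reduction for employed incontinent
patients, derived from women's working hours (38 → 30 h/week), while its
own cited survey figures put the impact at 8% for women versus 21% for men
in a cohort that is 80.87% female. Applied uniformly, 21.1% makes the
productivity component ≈ €1,300–1,600 per arm and pushes societal totals
about 40% below the published €1,937/€2,089/€1,960; the published totals
are consistent, across all three arms simultaneously, with the
sex-weighted reduction 0.8087×8% + 0.1913×21% = 10.49%. The package
therefore defaults to `hours_reduction_mode: sex_weighted` and retains the
uniform printed value as `hours_reduction_mode: uniform`. Under the default
the base-case societal totals come out ≈ €1,851/€2,054/€1,882 (−4.5%,
−1.7%, −4.0% against the published figures) with the published orderings
and dominance preserved under both modes; the exact component accruals
behind the published totals were never itemized and cannot be recovered, so
totals are validated with a tolerance band while orderings and dominance
are validated strictly.

## Cost-effectiveness comparison

Incremental cost and QALY are reference-minus-comparator. Dominance labels
follow standard CEA quadrant practice: "cost-saving" (cheaper, more
effective), "dominated", numeric ICER in the north-east quadrant, and an
explicitly flagged south-west ratio (cheaper and less effective) rather
than a bare number. The threshold check defaults to €30,000/QALY: ICERs
below it pass in the north-east quadrant, above it in the south-west.

## Sensitivity analysis

Every scenario re-runs the whole pipeline on a perturbed, re-validated copy
of the parameter set; the base set is immutable, so scenario runs are pure.
Perturbed probabilities are clamped to [0,1] with a logged warning. Three
scenarios need a non-obvious mechanism:

* **"% continent at week 12"** scales every arm's week-12 response fraction
  through a single engine-level multiplier rather than by multiplying and
  clamping each conditional column: per-cell clamping binds at different
  factors for different arms (fesoterodine's 0.9065 conditional saturates
  long before solifenacin's 0.8033) and silently reorders the arms, which
  is not what a uniform perturbation of the outcome means. The multiplier
  is capped so no response exceeds 1. All arms are scaled together; the
  published table does not say whether one arm or all were perturbed, and
  single-arm scaling of the reference arm makes it less effective than a
  comparator (a dominated, not an ICER, cell).
* **"% continent at week 52"** scales the week-52 persistence value.
* **"utility estimates"** scales the state-utility *increments* over the
  untreated baseline: multiplying utilities of ~0.95 by 1.25 would exceed 1
  and clamping would collapse every state to the same utility, zeroing all
  QALY gains — plainly not the intended scenario.

Under the packaged base case every ±25% perturbation of costs, utilization,
utilities, titration shares and week-52 continence leaves fesoterodine
cost-saving against both comparators, matching the published pattern. The
published grid additionally reports finite positive ICERs for the 12-week
horizon and the −25% week-12-continence rows (€574/€14,568 payer,
€9,106/€216,316 societal, €39,447/€17,814). These cells are not
reproducible from the printed inputs under any occupancy-weighting
convention: at 12 weeks the published ICER versus solifenacin implies an
incremental cost of ≈ +€2, i.e. continence-driven savings smaller than the
≈ €3 drug-price differential, whereas the printed pad/visit/comorbidity
rates generate ≥ €16 of savings at that margin; the −25% row likewise
implies a cost-versus-continence slope several times what the printed
inputs yield, with an intercept that cannot arise when zero-response arms
have near-identical occupancy. This package reports these scenarios as the
model actually evaluates them (cost-saving), and the discrepancy is
documented here rather than patched.

## Synthetic parameter generator and microsimulation oracle

`random_parameter_set` draws complete parameter sets for property testing.
Validity holds by construction: persistence values are drawn and sorted
non-increasing with the arm-specific week-8 value at least the shared
week-12 value; week-12 marginals are derived as conditional × week-8
response; skin/UTI expected event counts are the event probability times a
multiplier ≥ 1; utilities are drawn and ordered untreated ≤ incontinent ≤
continent. Default ranges are realistic neighbourhoods of the base case
(response 10–80%, persistence ≥ 30%, drug prices €0–5/day, etc.); any
quantity can be pinned through `GenerationRanges.overrides`, and point
ranges at the packaged values reproduce the base case exactly. A single
root seed spawns independent per-family substreams, so adding a family
never shifts existing draws.

`microsim` pushes n individual patients through the identical tree
(Bernoulli response → Bernoulli titration → Bernoulli conditional response
→ persistence survival via one latent uniform per patient, making
discontinuation monotone within a patient) and is the independent
statistical oracle: the cohort engine's occupancies are expectations of it,
and tests require agreement within 3 binomial standard errors at
n = 100,000 on the base case and on random parameter sets.

What the generator does **not** emulate: correlated responses across
checkpoints beyond the two printed conditionals, adverse-event-driven
discontinuation distinct from the persistence curve, between-checkpoint
status changes, heterogeneity in costs or utilities across patients, or
patient-level HRQoL instrument responses. Passing property tests therefore
demonstrate internal consistency of the cohort arithmetic under the model's
own assumptions, not external validity of those assumptions.

## Numerical choices

* Probabilities are fractions internally; parameter files carry the
  source's two-decimal percent precision and round-trip losslessly.
* The relative-risk derivation rounds to two percent-decimals half-up,
  after a six-decimal quantization that removes binary floating-point noise
  (0.2099 × 1.5 must round as 31.485 → 31.49).
* Solifenacin 10 mg is stored as printed (53.01/42.58) although the stated
  relative risk of 1.53 would give 53.03/42.60; the ±0.005 consistency band
  covers the drift.
* Degenerate inputs: zero week-8 response gives a two-branch tree with
  zero-filled responder branches; zero persistence at week 12 yields an
  all-untreated trajectory; dose mix is undefined (raises) when nobody is
  on treatment; all-equal utilities give exactly zero gain; all-zero prices
  and wage give exactly zero cost.
* The payer/societal identity (societal = payer + productivity) is exact by
  construction, not a tolerance assertion.

## Limitations

* The published cost totals are matched within a tolerance band, not
  exactly; the itemized accrual behind them is unrecoverable and the
  hours-reduction mode choice above is a calibration of one
  under-determined convention, transparently logged.
* Out-of-pocket expenses and caregiver time beyond the two productivity
  channels are excluded by design, as in the source analysis.
* The model is deterministic; no probabilistic sensitivity analysis or
  acceptability curves are provided.
* Utilities are consumed as fixed state values; no HRQoL-instrument scoring
  or utility-mapping regression is implemented (it would require
  patient-level trial data).
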