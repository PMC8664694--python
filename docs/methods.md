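# Methods

## Model and assumptions

`dialcost` implements a deterministic cost-minimization model from the
perspective of a single public payer. The modalities compared are assumed
clinically equivalent, so the analysis ranks them by cost alone. Costs are
per patient-year in one currency (the packaged book uses real 2019 Canadian
dollars), with no inflation adjustment, currency conversion or discounting:
the horizons of interest are months to a few years and undiscounted cash
streams are compared directly. Out of model scope are societal costs
(patient transportation, home utilities beyond those the program pays,
caregiver time), peritoneal-dialysis technique failure and
modality-switching costs, and any quality-of-life weighting.

A modality's cost structure has two parts:

- **Maintenance**: an ordered list of labelled annual cost lines, each
  carrying a category (`direct_hr`, `hr_adjunct`, supplies, drugs,
  equipment, sundry, utilities, water, capital, in-center backup runs).
  Payroll overheads are derived rows, not inputs: benefits and
  vacation/relief are fixed fractions `b` and `v` of the **direct-HR
  subtotal only**. Adjunct HR spending (staff mileage, parking, cellular
  phones) is wage-adjacent but carries no payroll overhead; modelling it as
  `hr_adjunct` and excluding it from the multiplier base is required to
  reproduce program accounting for assisted modalities, where such lines
  are material.
- **Training**: a one-time outlay of direct-HR lines (teaching is staff
  time) grossed up by the same `b` and `v`, plus a training duration `d`
  in months.

### Accumulated cost and the training convention

Accumulated cost over `t` months of therapy is

    A(t) = T + m · max(0, t − d)

where `T` is the training total (a lump sum at therapy start), `m` the
monthly maintenance rate (annual total / 12), and `d` the training
duration. The convention — training paid at `t = 0`, maintenance starting
only once training ends — is the unique simple one under which a
modality's reported accumulated costs at successive horizons are mutually
consistent in the reference data set; it makes `A` continuous,
non-decreasing and piecewise linear with one knot at `d`. The comparator
(in-center HD) trains nobody: `T = 0`, `d = 0`, a pure linear stream.

### Duration calibration

`d` is rarely published. Given a reference accumulated cost `A_ref` at time
`t_ref` (in the packaged book, the 3-month value), the unique duration
with `A(t_ref) = A_ref` is

    d = (T + m·t_ref − A_ref) / m,

valid when `T ≤ A_ref ≤ T + m·t_ref`. References outside that band are
rejected as inconsistent, naming the modality: above the ceiling would
imply negative `d`, below the floor cannot be reached by any `d` (the
curve never dips under its upfront cost). Calibration is resolved at
config load and again (idempotently) by `fit()`.

### Cost neutrality

For two trajectories the difference `A_a − A_b` is piecewise linear with
knots at `{d_a, d_b}`; the crossing solver walks the segments
`[0, d_min]`, `[d_min, d_max]`, `[d_max, ∞)` in exact decimal arithmetic
and returns the first time the *sign* of the difference changes. Tie
handling: starting equal at `t = 0` and diverging is not a crossing;
touching the other curve and returning to the same side is not a crossing;
if the curves coincide along a segment and the ordering flips beyond it,
the crossing is the start of the coincident stretch (the infimum time at
which the ordering changes). A pair that never changes sign is classified
`always_cheaper` / `always_costlier` (from the first trajectory's
perspective, with strict inequality somewhere) or `identical`.

### Analyses

- **Graduation savings**: difference of annual maintenance totals between
  an assisted modality and its self-care alternative, training excluded
  (reported to whole dollars).
- **Payoff time**: months for the maintenance differential to repay the
  target modality's training cost, `T_to / ((M_from − M_to)/12)`; refused
  when the differential is not positive.
- **One-way sensitivity**: the comparator's *monthly maintenance rate* is
  scaled by each factor (e.g. 0.75, 1.25); its training is zero so nothing
  else scales, and evaluated modalities are untouched.
- **Frequency scenario**: lines flagged `frequency_scaled` are multiplied
  by the ratio of new to old treatments per week. Defaults by category:
  medical supplies, water and in-center backup runs scale; fixed costs do
  not. Per-visit assistance staffing (licensed practical nurse, health
  care aide) also scales but that is a per-line flag set in the cost book,
  since the same roles appear as fixed allocations elsewhere.
- **Staff substitution**: mapped staffing lines are relabelled and scaled
  by an explicit `wage_ratio`. No default ratio is asserted; any ratio
  below 1 makes every assisted modality cheaper, which is the
  property-tested claim. The target label must not collide with an
  existing line label (labels are unique within a profile).

## Parameters

| parameter | units | default | why |
|---|---|---|---|
| `benefit_rate` (b) | fraction | 0.2015 | ratio of the derived benefits row to the direct-HR subtotal, constant across all 18 maintenance/training columns of the packaged book; user-overridable |
| `vacation_relief_rate` (v) | fraction | 0.1962 | same recovery for the vacation-and-relief row |
| `timepoints` | months | 3, 6, 12 | standard reporting horizons for accumulated cost |
| `sensitivity_factors` | — | 0.75, 1.25 | facility cost varied ±25%, the conventional one-way band |
| `treatments_per_week` | per week | 3 (HD), 7 (PD) | thrice-weekly hemodialysis, daily peritoneal dialysis |

## Numerical choices

Currency is `decimal.Decimal`. Cent rounding is half-up and applied at
each *derived row* (benefits, vacation/relief) before summing, mirroring
how printed cost tables are assembled; totals therefore agree with a
table's printed total only within about $0.05, since the printed rows are
themselves independently rounded. Whole-dollar reporting is half-up.
Months are real-valued decimals (no calendar conversion), reported to two
decimals. Trajectory arithmetic stays in `Decimal` end to end, so crossing
times are exact rational solutions of the segment equations rather than
float roots; the test suite checks them against an independent 0.001-month
dense-grid scan.

## The packaged Manitoba 2019 book and its known inconsistencies

The packaged fixture encodes a nine-modality renal-program cost book
(in-center HD, self-care CAPD/CCPD, conventional home HD, and full-,
partial- and complete-care assisted home HD and CCPD variants). Two
internal wrinkles are documented rather than forced:

- Summing the published line items yields direct-HR subtotals $0.01–0.02
  different from the published subtotal rows (independent rounding in the
  source tables); engine totals consequently sit within $0.05 of published
  totals, not exactly on them.
- The published neutrality months for the PD rows and the full-/complete-
  care home HD rows are not reproducible from the published cost columns
  and accumulated-cost table under any single training convention we
  could identify (they imply far smaller training durations than the
  3-month accumulated costs do). The conventional and partial-assist home
  HD rows are consistent and are the ones asserted; for the rest the
  solver is validated against dense-grid and generator-side oracles
  instead, and `d` remains a user-settable input for anyone wishing to
  impose other durations.

## Synthetic cost books

`dialcost.synth.random_costbook` generates random books that copy the
*structure* of a real one — several direct-HR lines that attract
overheads, an overhead-exempt adjunct line, non-HR lines, a single
training line, a training duration encoded as a calibration reference, and
a comparator whose monthly rate sits a random premium above the cheapest
modality so crossings exist. Draws are uniform over configured intervals
(defaults: 2–5 HR lines of $500–$20,000, non-HR lines of $100–$15,000,
training $0–$25,000, durations 0–2 months, comparator premium 5–80%);
the generator records ground-truth totals and trajectory parameters
computed by straight-line arithmetic at generation time, independent of
the engine. It emulates none of the correlation structure, category mix or
magnitudes of any real program, so passing property tests demonstrates
engine correctness (totals, overhead exclusion, calibration recovery,
crossing detection), not realism of any particular cost book.

## Problem sizes

The packaged analyses are desk-scale (9 modalities, ~130 cost lines) and
run in well under a second. Property checks use 300–1,000 random
trajectory pairs against the 0.001-month grid oracle over [0, 600] months
and 60–200 random cost books; these sizes give dense coverage of the
segment/tie cases while keeping the whole suite under half a minute.

## Limitations

Beyond the scope exclusions above: the model has no patient population,
graduation rates or modality-switching dynamics (single-patient streams
only); frequency scenarios assume perfectly proportional scaling of the
flagged lines; staffing substitution assumes the replacement role performs
identically; and calibration trusts the reference accumulated values —
garbage references produce garbage durations, subject only to the
feasibility band check.
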