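# dialcost

Deterministic cost-minimization modelling of dialysis modalities for
single-payer health systems.

Kidney failure programs must choose how to deliver life-sustaining dialysis:
in a facility (in-center hemodialysis), at home under full patient self-care
(home HD, CAPD/CCPD peritoneal dialysis), or at home with paid nursing and
aide assistance. When the modalities are clinically equivalent the question
is purely economic, but the comparison is not a single number: home
modalities trade a one-time training investment and a training period for a
lower running cost, so which option is cheapest depends on how long the
patient stays on therapy. `dialcost` is for health-economics analysts and
renal-program planners who need that comparison as a reusable, config-driven
engine rather than a spreadsheet.

## The model

Each modality is a *cost book* column: labelled annual cost lines
(staffing, supplies, drugs, equipment, capital, ...) per patient-year.
Payroll overheads are derived, not entered: with direct human-resources
subtotal `H` and overhead rates `b` (benefits) and `v` (vacation and
relief),

    benefits = round_cents(b · H),   vacation_relief = round_cents(v · H)

and the annual maintenance total is the sum of all lines plus both derived
rows. Training is a one-time outlay `T` of direct-HR lines grossed up the
same way. The accumulated cost of a modality over `t` months of therapy is
piecewise linear,

    A(t) = T + m · max(0, t − d)

with monthly maintenance rate `m` (annual total / 12) and training duration
`d` months. `d` is rarely reported directly; the model calibrates it from a
reference accumulated cost (`A(t_ref) = A_ref` gives
`d = (T + m·t_ref − A_ref)/m`). Cost neutrality between two modalities is
the first time the sign of `A_a(t) − A_b(t)` changes, solved exactly on the
linear segments; a modality that never crosses is reported as dominated
(or dominating). On top sit one-way sensitivity (scaling the comparator's
maintenance rate, e.g. ±25%), graduation savings (annual maintenance
differential of assisted vs self-care), payoff times
(`T_to / ((M_from − M_to)/12)`), and what-if scenarios for treatment
frequency and staff substitution. No discounting is applied; amounts are
plain decimals at cent precision.

The packaged data set is a nine-modality Manitoba renal-program cost book
in real 2019 Canadian dollars (comparator: in-center HD, which has no
training cost), with `b = 0.2015` and `v = 0.1962`.

## Worked example

```python
from decimal import Decimal
from dialcost import CostMinimizationModel, manitoba_2019, round_dollars

res = CostMinimizationModel(manitoba_2019()).fit()
print(res.maintenance_totals[["in_center_hd", "home_hd_conventional"]])
print(res.neutrality().to_string(index=False))
print("graduation saving, full-assist CCPD -> self-care:",
      round_dollars(res.graduation_savings("ccpd_full_assist", "ccpd")))
print("payoff, complete-care home HD -> self-care:",
      res.payoff_time("home_hd_complete_care",
                      "home_hd_conventional").quantize(Decimal("0.01")),
      "months")
```

prints

```
in_center_hd            67415.57
home_hd_conventional    36618.39
Name: annual_maintenance, dtype: float64
             evaluated   comparator                        months                  months_x0.75 months_x1.25
                  capd in_center_hd                          2.03                          4.42         1.32
                  ccpd in_center_hd                          3.28                         26.01         1.75
  home_hd_conventional in_center_hd                          9.44                         20.85         6.10
   home_hd_full_assist in_center_hd                          0.05                          0.07         0.04
home_hd_partial_assist in_center_hd                          7.12                         27.43         4.09
 home_hd_complete_care in_center_hd                          0.05                          0.07         0.04
   ccpd_partial_assist in_center_hd comparator always less costly comparator always less costly         0.62
      ccpd_full_assist in_center_hd                          0.05 comparator always less costly         0.04
graduation saving, full-assist CCPD -> self-care: 27585
payoff, complete-care home HD -> self-care: 10.89 months
```

Reading it: in-center HD costs $67,416/year to run while conventional home
HD costs $36,618 but demands $25,485 of upfront training — a patient must
stay on home HD 9.44 months before the investment is recouped (20.85 months
if facility costs were 25% lower, 6.10 if 25% higher). Assisted CCPD runs
costlier per month than in-center HD and never breaks even at base facility
cost. A patient graduating from full-assist CCPD to self-care saves $27,585
per year, and complete-care home HD patients who graduate to self-care
recover the self-care training cost in 10.89 months.

## Command line

```sh
dialcost fixture book.yaml          # write the packaged cost book
dialcost validate book.yaml
dialcost totals book.yaml
dialcost trajectory book.yaml --at 3,6,12
dialcost neutrality book.yaml --sensitivity 0.75,1.25
dialcost scenario book.yaml --frequency 3.5
dialcost scenario book.yaml --substitute "Licensed practical nurse:Health care aide:0.7"
```

Any subcommand takes `--csv DIR` to write CSV tables instead of aligned
text; exit status is nonzero on validation errors.

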