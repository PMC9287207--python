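# Methods

## Scope and structure

The package evaluates two axillary staging strategies for clinically
node-negative (cN0) breast cancer in a cohort of 1000 women: SLNB for all
(standard of care) versus SLNB restricted to patients with a positive result
from a noninvasive nodal staging prediction model (NILS), at three
sensitivity/specificity operating points. It is a deterministic
cohort-expectation model — a diagnostic decision tree feeding a yearly-cycle
state-transition model — with a seeded individual-level microsimulation used
purely as a validation oracle.

## Diagnostic pathway

NILS and SLNB results are modelled as conditionally independent given true
nodal status; the tree arithmetic requires no correlation parameter and none
is available. pN+ means micro- or macrometastases; isolated tumor cells are
counted as pN0 and receive no special handling. SLNB specificity below 1 is
supported throughout (false positives proceed to ALND) although the default
fixes it at 1 — generality costs nothing and enables sensitivity analyses.
Patient counts shown in tables are cohort-size × fraction rounded half-up for
display only; all computation uses unrounded fractions.

## Treatment and complications

Diagnosed-negative patients — true negatives and false negatives alike —
receive the node-negative bundle; therapy "omission" for false negatives is
exactly this assignment, with its survival consequences expressed as hazard
ratios in the progression model. A false-negative stratum is expanded into
the 2³ combinations of omitted radiotherapy (mastectomy only; after
breast-conserving surgery radiotherapy is given regardless of nodal status),
omitted chemotherapy (the excess of the diagnosed-positive over the
diagnosed-negative uptake share, assuming nested uptake) and omitted extended
endocrine therapy (the full diagnosed-positive share), treated as
independent; each combination gets the product of its hazard ratios. This
exact enumeration, rather than an averaged hazard ratio, is what makes the
cohort expectation equal the microsimulation mean, since transition
probabilities are nonlinear in the hazard ratio.

Chemotherapy, extended endocrine and HER2 therapy enter as cohort shares
because receptor status is not modelled individually. Seroma and infection
carry one-off costs but no utility decrement; decrements exist only for
chemotherapy, recurrence and lymphedema. The breast-surgery mix of the pooled
cohort is a parameter (default 0.65 breast-conserving surgery, a typical
contemporary share); subgroup analyses set it to 1 or 0.

## Progression

Cycle length is 1 year with payoffs counted at the end of each cycle lived;
no half-cycle correction is applied (the convention is localized in
`progression.run_cohort` and `CohortTrace.life_years`). States are
disease-free, recurrence, breast-cancer death and other-cause death.
Recurrence is an absorbing morbidity state covering recurrent and metastatic
disease jointly; breast-cancer mortality acts from both alive states at the
same modified rate, because only pooled 10-year mortality and recurrence
figures are available, not a recurrence→death submodel. Yearly rates are
constant over the 10-year disease window (derived from 10-year cumulative
figures via 1−(1−P₁₀)^(1/10)); after year 10 only all-cause mortality
applies, to the life-table terminal age of 100 (life-long horizon).
Hazard modifiers apply to both mortality and recurrence.

Competing risks within a cycle are resolved by converting yearly
probabilities to constant hazards, combining them, and allocating exits
proportionally to cause-specific hazards. This is order-independent, but it
has one visible consequence: raising a *non-fatal* competing hazard
(recurrence) can marginally lengthen life because a within-cycle recurrence
defers the death decision to the next cycle. The microsimulation uses the
identical convention, so the two routes agree by construction of the
convention, while the simulation still independently verifies the cohort
bookkeeping.

Default cohort entry age is 60 (median breast-cancer diagnosis age range);
it is configurable and all-cause mortality is age-adjusted from the life
table.

## Costs and utilities

One-off costs (breast surgery, SLNB, ALND, expected complication costs,
radiotherapy, chemotherapy and HER2 therapy priced as courses) fall at cycle
0 undiscounted. Recurring costs are extended endocrine therapy in cycles 6–10
("beyond 5 years") for the diagnosed-positive ER+ share while alive, a
one-off cost at recurrence onset, and a yearly metastatic-care cost while in
the recurrence state. Costs are in EUR as configured, with no inflation or
currency conversion.

Utilities are an age-step baseline (population EQ-5D-style values declining
from 0.90 to 0.69 across decades) minus decrements: chemotherapy during the
treatment year only (standard single-year convention), recurrence while in
that state, lymphedema life-long from surgery for the affected share. The
per-profile utility is clamped below at 0; at the shipped parameter values
the clamp never binds, so total QALYs are exactly affine in the lymphedema
decrement — the property the break-even analysis exploits. Costs and QALYs
(and reported life years) are discounted at 3% per year.

## Threshold analysis

Incremental QALYs Δ(d) as a function of the lymphedema decrement d are
affine and increasing (triage always leaves fewer lymphedema-affected
person-years), so the per-scenario break-even point solves a linear equation
built from evaluations at d = 0 and d = 0.1 — both inside the unclamped
region — and the overall threshold is the largest root, floored at 0.
Bisection (tolerance 1e-6) is retained as a cross-check. If some scenario has
no root in [0, 1] the threshold is reported as unattainable.

## Synthetic parameters

Printed inputs (prevalence 0.32; SLNB 92.3%/100%; the three NILS operating
points; lymphedema risks 0.4/6.3/22.3%; discount rate 3%; the 0.1 lymphedema
decrement; the 10-year window; per-1000 reporting) are fixed with
`PAPER_PRINTED` provenance and are never perturbed. Everything standing in
for the unavailable supplementary inputs — costs, therapy uptake shares,
hazard ratios (1.60 omitted radiotherapy, 1.30 chemotherapy, 1.15 extended
endocrine, in meta-analytic ranges), yearly base rates (from 10-year
cumulative mortality 10% and recurrence 15%), chemotherapy and recurrence
decrements (0.10, 0.15) — is tagged `SYNTHETIC_DEFAULT`. These defaults were
chosen once, as plausible values for a contemporary Swedish-style setting,
and reproduce the qualitative result pattern (triage cost-saving in all
scenarios; QALY gain with the 0.1 decrement, loss without; larger savings
under breast-conserving surgery); that is a calibration of stand-ins, not
ground truth, and the exact monetary/QALY magnitudes from the original
inputs are reproducible only by supplying those inputs through the
configuration file.

The life table is a synthetic Gompertz table, q(age) = 1 − exp(−a·e^(b·age))
with (a, b) = (2e-5, 0.10) and q(100) = 1 — approximating a high-income
female table — rather than a bundled national table, avoiding licensing
questions; the two-column TSV format accepts a real table as a drop-in.
`perturbed_parameter_set` provides seeded stress variants: synthetic scalars
scaled by log-uniform factors, hazard ratios perturbed on their excess over 1
and probabilities clipped to [0, 1] so every variant validates.

## What the synthetic data does and does not show

Passing tests demonstrate internal correctness (tree arithmetic, competing
risks, discounting, linearity, oracle equivalence) and the direction of
every published effect under plausible inputs. They do not validate the
magnitude of real-world costs or QALY changes, which depend on the original
cost/utility inputs; nor does the model capture ER/HER2 subtypes as states,
neoadjuvant pathways, treatment non-adherence, or any recurrence→death
submodel beyond the pooled rates.

## Problem sizes

The cohort model is exact expectation (no sampling), run to age 100 in
yearly cycles. Microsimulation checks use 10⁵ patients, which puts 4
standard errors at roughly 1% of the cost mean and tighter for QALYs —
ample to detect bookkeeping errors while keeping each run around a second.
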