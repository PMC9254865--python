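# Methods

## Model structure

The core is a three-state partitioned survival model (PSM). State
membership at time t is read directly off the two endpoint curves:
progression-free occupancy is min(S_PFS, S_OS), the dead compartment is
1 − S_OS, and the progressed-and-alive compartment is the band between the
curves. No transition probabilities are estimated; the PSM's defining
assumption is that the two marginal curves jointly determine occupancy,
which is why the synthetic-data generator enforces PFS ≤ OS record-wise.

Discretization: 21-day cycles (the pembrolizumab dosing interval, to which
the per-cycle cost inputs are keyed) over a 5-year base-case horizon, both
configurable. Occupancy is evaluated at cycle midpoints — equivalent to a
half-cycle correction — and discounted at the midpoint time with
(1 + r)^(−t), r = 5%/year by default (conventional band 0–8%). Incident
deaths per cycle are the OS drop across the cycle's boundaries; they
telescope exactly to 1 − S_OS(T). Rows of the occupancy trace sum to 1.0
exactly by construction (the dead compartment is computed as the
complement of the alive mass), and a PFS curve that crosses above OS —
possible with independently fitted or digitized curves — is clamped to OS
with a warning rather than producing negative progressed occupancy.

## Survival curves

Six parametric families are supported, in the parameterizations standard
for HTA survival extrapolation: exponential (rate), Weibull (shape,
scale), Gompertz (real-valued shape, rate; a negative shape yields an
improper plateau, which is accepted), log-logistic (scale = median,
shape), log-normal (mu, sigma on log time), and the three-parameter
(mu, sigma, q) generalized gamma in log-time form, with the |q| < 1e-5
branch evaluated as its log-normal limit for numerical stability.

Fitting maximizes the right-censored log-likelihood
sum(event·ln f + (1−event)·ln S) with scipy, on a transformed scale (log
for positivity-constrained parameters), from several deterministic
moment-based starts (Nelder–Mead polish followed by L-BFGS-B). The
convergence flag checks the gradient norm at the optimum relative to the
log-likelihood magnitude; non-convergence is flagged, never raised. Model
selection takes the minimum AIC or BIC among converged fits, breaking
exact ties by fewer parameters and then a fixed family order. Curve times
are in months (the trial scale); the engine converts to model years at its
boundary (365.25/12 days per month). Subgroup and comparator curves are
derived by proportional hazards, S'(t) = S(t)^HR, for which the
cumulative-hazard ratio equals HR identically.

lifelines serves as an independent cross-check in the test suite (its
Weibull MLE and Kaplan–Meier estimator against ours); the fitting itself
is done in-package because lifelines does not cover the Gompertz family
or this generalized-gamma parameterization. The product-limit estimator
used for validation (`km_estimate`) is lifelines' KaplanMeierFitter.

## Pseudo-IPD reconstruction

Published figures give only a digitized KM step function and a
number-at-risk table. Reconstruction inverts the product-limit estimator
interval by interval: within each risk interval an integer censor count is
iterated until the implied at-risk count at the next published time equals
the published value exactly; censoring times are placed at equally spaced
points inside the interval (deterministic, rather than random as in some
implementations), and per-step event counts come from the KM ratio with
remainder-carrying rounding so interval totals are preserved. Because
integer event rounding can leave a ±1 residue that no censor count
repairs, the iteration detects cycles and then rebalances the interval's
tail allocation (extra censorings just before the interval end, or
retraction of the latest events) so the published at-risk counts always
match exactly; genuinely unreachable counts raise an error naming the
interval. After the last risk entry no censoring is assumed unless a total
event count is supplied, in which case residual events/censorings at the
curve end are balanced to match it. Ties between an event and a censoring
at the same time follow the standard KM convention (event first).

On synthetic fixtures (n = 300, 3-month risk grid) the KM estimate of the
reconstruction tracks the input curve within 0.02 sup-norm; this is
asserted in the test suite.

## Synthetic trial generator

No patient-level or digitized data accompany the published analysis, so
the generator emulates the trial from its printed summaries. Defaults:
three arms of 355 patients (the trial's scale); PFS truth curves are
Weibull with shape 1.2 calibrated so S(median) = 0.5 exactly at the
printed medians (23.9 / 14.7 / 9.2 months) — shape 1.2 gives a single-knob
calibration with mildly increasing hazard, typical of first-line PFS;
reference OS is exponential, anchored so the engine's discounted reference
life-years over 5 years equal the published 2.83 (the sunitinib OS median
was not reached in the trial, so no median is available to calibrate on);
comparator OS applies the printed hazard ratios (0.66, 1.15). Sampling is
inverse-transform with one common uniform draw per patient for both
endpoints, which preserves each marginal exactly while guaranteeing
PFS ≤ OS; administrative censoring is max follow-up (36 months) minus a
uniform accrual offset (12 months of accrual). Both follow-up numbers are
package choices of trial-like magnitude.

What the generator does not emulate: the trial's actual censoring pattern,
stratification, covariates, non-proportional hazards, or the digitization
noise of a real figure. Passing round-trip and recovery tests therefore
demonstrate internal consistency of the pipeline, not fidelity to the
unpublished trial data.

## Costing and utilities

All amounts are RMB. First-line acquisition cost applies while
progression-free (treat-to-progression): oral components are unit price ×
units/day × cycle days, with sunitinib's 4-weeks-on/2-weeks-off schedule
handled as the steady-state dosed-day fraction 28/42; pembrolizumab is
billed per cycle at 100 mg × the per-mg price, following the source's
stated dosing. Because the published price table quotes per-tablet prices
of unstated strength, the fixture pins the implied units per day so daily
costs are 540 (lenvatinib 20 mg), 486 (lenvatinib 18 mg), 130 (everolimus
5 mg) and 392 (sunitinib 50 mg on dosed days) — an explicit, auditable
knob. Progressed patients split between subsequent therapy (per-cycle cost
weighted by each arm's published uptake: 54.9% / 68.2% / 71%) and best
supportive care (353/cycle) until death; follow-up (474/cycle) and
hospital management (142/cycle) apply to both alive states; terminal care
(12,721) is billed on incident deaths; grade ≥3 adverse events contribute
a one-off expected cost and a one-off QALY loss (disutility 0.157 × total
incidence capped at 1 × 4-week duration) at model entry. The published
"probability of treatment discontinuation due to AE" is housed and
sweepable but not applied in the base case, since its mechanism is not
specified in the source; an optional mode phases it into first-line drug
cost over a configurable ramp. Utilities: 0.82 progression-free (0.73 for
sunitinib), 0.66 progressed.

Two published ranges are treated as typographical errors: the terminal-care
range (printed upper bound 152,665 against a base of 12,721) and the
lenvatinib + everolimus subsequent-cost range (printed high-to-low); both
use ±20% of base / the reordered bounds. Grade ≥3 AE incidences are not in
the published input table; the fixture ships synthetic placeholders of
trial-like magnitude, clearly labelled, that contribute only a small
one-off term.

## Decision analysis

ICERs are pairwise against the reference with dominance labelling. The
one-way DSA sets each parameter to its published low/high bound (others at
base) and sorts tornado bars by ICER-interval width; the discount rate
(0–8%) is varied here but, as published, held fixed in the PSA. The PSA
samples costs from gamma and bounded quantities from beta distributions,
moment-matched to mean = base and sd = range/3.92 (ranges read as central
95% intervals), on fixed base-case curves — survival-parameter uncertainty
is deliberately out of PSA scope, matching the source's design. CEACs
report, per willingness-to-pay point (default grid 0 to 1,000,000 RMB/QALY
in 10,000 steps), the fraction of 10,000 iterations in which each strategy
has the highest net monetary benefit (probabilities partition to 1);
pairwise CEACs and incremental-plane quadrant shares are also provided.
Scenarios re-run the model at 5/10/20-year horizons (reporting the share
of discounted cost accrued by year 5) and scale the first-line
pembrolizumab price by 0–75% (the ICER is affine in that price, which the
test suite checks to machine precision). Subgroups assume all arms share
the reference baseline curves and apply subgroup hazard ratios to the
comparator; the shipped subgroup HRs are synthetic demonstrations because
the source does not print its subgroup HRs.

Determinism: a single master seed is split into named substreams
(simulate, psa) by hashing, so every stochastic stage is bit-reproducible
from one flag; all derived seeds are below 2^31.

## Numerical choices

- Cycle grid: ceil(horizon/cycle) cycles; the last boundary may overshoot
  the horizon by a partial cycle (≤ 21 days), and costs accrue on full
  cycles.
- Gompertz with a → 0 and generalized gamma with q → 0 use limit-safe
  branches; survival evaluations are clipped to [0, 1] and inverse
  survival returns +inf beyond an improper plateau.
- The life-year anchor for the reference OS curve is solved by bisection
  against the engine's own discretized life-year computation, so the
  anchor is exact under the same grid the model uses (2.83 to 1e-9).
- Problem sizes in the shipped analyses — 87 cycles (5 y), 10,000 PSA
  iterations, 355 patients per simulated arm — are the study's own scale;
  the full acceptance recomputation runs in seconds.

## Known limitations

- Proportional hazards on a single reference curve cannot reproduce a
  comparator that is OS-inferior early but LY-superior over the horizon;
  with HR_OS = 1.15 the lenvatinib + everolimus arm is strictly
  OS-inferior here, so its incremental QALYs are small and its ICER is
  highly sensitive to the denominator.
- Under the stated 100 mg-per-cycle pembrolizumab dosing and
  treat-to-progression, first-line drug cost — and hence the incremental
  cost of the pembrolizumab combination — is substantially lower than in
  analyses that fit heavier-tailed PFS curves to digitized trial data or
  use the trial's 200 mg dose; the qualitative conclusion (ICERs above 3×
  GDP per capita) is unchanged.
- No background general-population mortality, tunnel states, vial sharing,
  dose reductions, or cure fractions; no spline or covariate survival
  models; curves are fixed in the PSA.
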