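# Methods

## Model structure

The decision model is a deterministic three-state Markov cohort:
disease-free survival (DFS), progressive disease (PD), and death. The
whole cohort starts disease-free. The cycle length is 21 days, the
horizon 10 years (`ceil(3652.5 / 21) = 174` cycles), and both costs and
QALYs are discounted at 3% per year. Time is kept in months internally,
with 1 month = 365.25/12 days, so one cycle is u ≈ 0.6899 months.

Each arm carries two Weibull survival curves, S(t) = exp(−λt^γ): one for
DFS and one for overall survival (OS). The per-cycle conditional event
probability for the cycle ending at t is
P(t) = 1 − exp[λ(t−u)^γ − λt^γ] = 1 − S(t)/S(t−u). The transition
structure is:

* Death probability d(t), from the OS curve, applies to **both** alive
  states. Consequently modelled cohort survival (1 − p_death) equals the
  fitted OS curve at every cycle boundary — a built-in validation used by
  the tests at 1e−10.
* The DFS-event probability e(t), from the DFS curve, counts both
  progressions and deaths (the trial's DFS endpoint). DFS→Death is
  min(d, e) and DFS→PD is max(0, e − d), which avoids double-counting
  deaths. Whether the original model allowed direct DFS→Death is not
  documented; this structure is our choice and is stated as such.
* PD→Death is d; death is absorbing.

Costs and utilities accrue on start-of-cycle occupancy, transitions apply
at cycle end, and the discount factor uses start-of-cycle time,
(1 + r)^(−(k−1)·21/365.25) for cycle k. No half-cycle correction is
applied by default (the common default of the modelling environment this
style of analysis is usually built in); `run_cohort(half_cycle=True)`
switches to averaging start- and end-of-cycle occupancy. Halving the
cycle length moves total discounted QALYs by well under 1% at the default
calibration, so the discretisation choice is immaterial at this horizon.

## Parameters

Baseline values (USD, utilities on [0, 1]):

| parameter | gefitinib | chemotherapy | notes |
|---|---|---|---|
| drug cost per cycle | 21 × $23.33 = $489.93 | $95.60 | see dosing below |
| treatment duration | 24 months (35 cycles, last prorated) | 4 cycles | |
| follow-up (DFS state) | $55.60/cycle | $55.60/cycle | surveillance of disease-free patients |
| supportive care (PD state) | $337.50/cycle | $337.50/cycle | |
| PD entry (one-off) | $1,877.25 | $1,877.25 | charged to incident PD fraction |
| AE management | $507.40/cycle × incidence | same | treatment cycles only |
| grade 3–4 AE incidence | 0.12 | 0.48 | |
| DFS utility | 0.80 (oral) | 0.76 (intravenous) | |
| PD utility | 0.70 | 0.70 | |
| AE disutility | 0.0731 | 0.0731 | text value kept over the rounded 0.07 table entry |

Dosing uses a reference patient (1.64 m, 65 kg, BSA 1.72 m²). Vial-based
drugs are rounded up to whole vials per administration with no sharing:
vinorelbine 25 mg/m² → 43 mg → 5 × 10 mg vials × $8.16 on days 1 and 8,
cisplatin 75 mg/m² → 129 mg → 5 × 30 mg vials × $2.80 on day 1, giving
$95.60 per chemotherapy cycle. Gefitinib's 24-month course spans 730.5
days = 34 full cycles plus 16.5 days, prorated by day in cycle 35.
AE burden is applied as an expected value (incidence × cost, incidence ×
disutility) uniformly over treatment cycles; only aggregate incidences
are available, and this is the simplest allocation consistent with them.

Survival calibration: the analysis this model re-implements fitted
Weibull curves to digitized trial Kaplan–Meier coordinates, but neither
the coordinates nor the fitted (λ, γ) are public. The bundled
configuration therefore calibrates exponential curves (γ = 1) to the
printed medians via λ = ln 2 / median: DFS 30.8 / 19.8 months and OS
75.5 / 62.8 months. This reproduces the qualitative conclusion (positive
incremental QALY, ICER below WTP) but not the published absolute totals;
exact reproduction requires the original digitized curves, which can be
supplied as `km_csv` inputs per curve.

## Kaplan–Meier fitting and synthetic data

`fit_weibull_to_km` uses the exact log-log linearisation
log(−log S) = log λ + γ log t, solved by (optionally at-risk-weighted)
least squares over points with 0 < S < 1 and t > 0; points at S = 1 or
t = 0 are dropped, duplicate digitized times keep the last (lowest)
survival value, and at least three usable points are required. On
noise-free Weibull coordinates the fit is exact to solver precision.
Log-log least squares is preferred to maximum likelihood because
digitized coordinates carry no individual-level data.

The synthetic generator draws event times by inverse transform,
t = (−ln U/λ)^(1/γ), with independent exponential censoring plus an
administrative cutoff at 80 months (the trial's median follow-up), and
summarises samples with the product-limit estimator (lifelines). The
closure simulate → KM → fit recovers parameters within 10% at n = 2,000.
The generator emulates the shape of trial survival data, not its risk-set
tables, staggered accrual or stratification — so passing tests show the
pipeline's statistical machinery is sound, not that real digitized curves
would yield any particular ICER.

## Outcomes and sensitivity analyses

ICER = ΔC/ΔE, ACER = C/E per arm, NMB = WTP·E − C with WTP defaulting to
$30,828/QALY (three times per-capita GDP; overridable per run). When one
arm is cheaper and more effective the ICER is not printed as a ratio; a
dominance label is reported, and the cost-effectiveness verdict is always
the NMB ordering.

OWSA varies costs ±30% and utilities/probabilities ±20% (clamped to
[0, 1]), one at a time, and reports incremental NMB at the default WTP;
the tornado outcome metric is not documented in the original analysis,
and incremental NMB is the standard choice that remains defined when the
ICER is not. PSA samples costs from gamma and utilities/probabilities
from beta distributions, moment-matched to the base value and a standard
error. The original dispersion assumptions are unpublished; each
parameter's deterministic range is read as a 95% central interval,
se = (high − low)/(2·1.96), overridable per parameter. Survival enters
the sensitivity analyses as each arm's base per-cycle event probability
(a genuine probability, hence beta-distributed), converted internally to
a multiplicative factor on the per-cycle probabilities and clamped to
[0, 1]. The AE disutility is sampled as a beta on its magnitude and
applied as a decrement. Sampling order is fixed by sorted parameter name
from a single seeded generator, so draws are reproducible and invariant
to configuration reordering; the CEAC grid spans 0 to 2× WTP in 100 steps
and always includes $1,500 and $30,828.

## Numerical choices

* `expm1` is used for every 1 − exp(·) so small per-cycle probabilities
  keep full relative precision.
* The oracle identity P(t,u) = 1 − S(t)/S(t−u) is verified to 1e−12
  relative error on grids restricted to cumulative hazard λt^γ ≤ 8
  (survival ≥ ~3×10⁻⁴); beyond that the ratio form itself loses floating-
  point precision to cancellation, while the implementation's exponent-
  difference form remains stable.
* Occupancy is propagated as exact complements (p_death = 1 − p_dfs −
  p_pd), keeping row sums at 1 to machine precision over 174 cycles.
* Near-degenerate beta dispersions are capped at parameter 10⁷ with a
  warning; zero dispersion short-circuits to the base value.
* Monetary outputs are rounded to cents only at CSV/JSON serialization;
  all internal arithmetic is double precision.
* Invalid sampled parameter sets in the PSA are resampled, at most 100
  times per draw.

## Problem sizes

Defaults follow the study design: 174 cycles × 2 arms for the base case,
22 tornado parameters (2 model runs each), 1,000 PSA iterations, and
n = 2,000 subjects (10% tolerance) for the parameter-recovery check, with
n up to 100,000 in distributional tests. The full test suite and the
acceptance script each run in a few seconds on one CPU.

## Known limitations

* Cohort-level expectation only; no microsimulation or individual
  heterogeneity.
* PD is costed as a one-off entry cost plus uniform supportive care; no
  post-progression treatment lines.
* No time-varying utilities beyond the on-treatment AE decrement.
* Two arms only; no efficiency frontiers or extended dominance.
* No expected-value-of-perfect-information analysis and no correlated
  parameter sampling.
* Costs and effects reflect the Chinese health-care system circa the
  source trial; the bundled exchange rate (6.8409 CNY/USD) is metadata,
  not applied arithmetic.
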