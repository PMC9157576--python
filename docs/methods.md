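# Methods

## Model

The package implements a two-state (survive/die) Markov cohort model
comparing supplemental home parenteral nutrition (sHPN) plus dietetic
counselling against best-practice nutritional care in incurable
gastrointestinal cancer, from the Chinese healthcare perspective. The cohort
advances in 6-week (42-day) cycles over a 5-year horizon
(43 = ⌊5 × 365.25 / 42⌋ cycles).

Overall survival in each arm follows a Weibull law S(t) = exp(−λ t^γ) with
time t in model units of `time_unit_days` days. The probability of dying in
the cycle ending at t is

    P(t) = 1 − exp(λ[(t − u)^γ − t^γ]) = 1 − S(t) / S(t − u),

with u the cycle length in model units, so the alive fraction at the start
of cycle k is exactly S(k·u) (the per-cycle survivals telescope). Both arms'
base-case (γ, λ) pairs are < 1, implying decreasing hazards.

Costs (US dollars, converted from CNY at 7.012 before entering the
configuration; the engine never applies an exchange rate) are either
one-time — accrued at model start, full cohort weight, undiscounted — or
per-cycle — accrued each cycle within an applicability window, weighted by
the fraction alive at cycle start. QALYs accrue per cycle as
alive × utility × (42/365.25). Cycle k uses the utility measured at the
visit that closes it (visit k+2), with the visit-5 value carried forward;
baseline utility describes the pre-model state and is never accrued. Both
value streams are discounted at 3 % per year pro-rated by exact day counts,
(1.03)^(−42k/365.25). No half-cycle correction is applied in the reference
convention; a `half_cycle` switch averages start- and end-of-cycle
membership instead.

## Outcomes

Primary: per-arm discounted totals (C, E), increments ΔC and ΔE, the ICER
ΔC/ΔE with a dominance class, net monetary benefit NMB(λ) = λ·ΔE − ΔC at
the willingness-to-pay threshold λ = $29,307/QALY (three times per-capita
GDP), and the *headroom* λ·ΔE − ΔC — the largest additional one-time
intervention cost (e.g. a catheter-care training fee) that keeps the ICER
at or below the threshold.

Secondary: ICERs per effect metric (quality of life, BMI, fat-free mass,
fat-free mass index, handgrip strength, 6-minute-walk distance) at each
visit v ∈ {2..5}. ΔE_v is the between-arm difference in change from
baseline at visit v. ΔC_v is the incremental discounted cost from model
start through visit v (visit v closes cycle v−2, so v−1 cycles have
elapsed). Because the metrics are measured in patients attending the visit
— survivors by construction — the default costing is *per surviving
patient*: recurring items accrue at full weight over the elapsed cycles
(each survivor paid every cycle's cost), discounted as in the primary
analysis. The alive-weighted cohort alternative (`costing="cohort"`) is
about 2.7 % lower by visit 3 and diverges further at later visits. Negative
ratios (intervention worse on the metric while costing more) are passed
through with their sign but flagged; units ride on every result so $/kg and
$/m cannot be compared silently.

## Time-unit conventions and calibration

The published Weibull shape/scale pairs come without a stated time unit,
and no natural unit reproduces the reported medians of 168/169 days (the
implied medians are 118.7/125.1 days for a 7-day unit, 237.5/250.2 for
14-day, 712.4/750.7 for 42-day). Likewise the published per-cycle costs do
not say whether intervention-linked items stop at the end of the 24-week
treatment window. The package therefore (a) exposes `time_unit_days` and a
`calibrate_scale_to_median` helper rather than guessing a convention, and
(b) provides `convention_scan`, which re-runs the base case over
{7, 14, 42}-day units × {4 cycles, unbounded} treatment duration and ranks
configurations by their maximum relative deviation from the published
per-arm totals (carried as reference metadata in the fixture, never read by
the engine). Under the fixture the minimizing convention is a 14-day unit
with treatment-linked costs stopping after 4 cycles (max deviation 18.9 %).
Early-horizon quantities are convention-insensitive: the visit-2 and
visit-3 quality-of-life ICERs reproduce the published values within 0.3 %
under the reference convention (42-day unit, unbounded costs).

## Sensitivity analysis

One-way: each parameter is pushed to the ends of its fluctuation band —
±50 % for costs, ±30 % for utilities and for the Weibull (shape, scale)
pair — holding everything else at base. Cost items carried identically by
both arms (supportive care, follow-up, readmission) are varied jointly as
one shared parameter; each arm's utility schedule and its (shape, scale)
pair are grouped multipliers (utilities cap at 1). Entries are ranked by
**NMB spread** at the threshold rather than ICER spread: raising the
comparator's utilities pushes ΔE across zero, the ICER flips sign and its
spread becomes meaningless, whereas the NMB is linear in the perturbation.
Under this ranking the sHPN utility group is the most influential
parameter, matching the qualitative published finding; `rank_by="icer"`
restores the raw ICER sort.

Probabilistic: 1,000 Monte Carlo iterations, each a full two-arm model
evaluation on an independent joint draw — utilities and Weibull shape/scale
from beta distributions (all base means lie in (0,1); a mean ≥ 1 raises
rather than silently switching family), costs from gamma. Moments are
matched to the fluctuation band read as a central 95 % interval:
σ = m·f/1.96 (beta: ν = m(1−m)/σ² − 1, α = mν, β = (1−m)ν; gamma:
k = (1.96/f)², θ = m/k). The `two_sd` option reads the band as m ± 2σ
instead. A master seed spawns per-iteration substreams
(`numpy.random.SeedSequence`), so results are reproducible and independent
of evaluation order. The acceptability curve reports P(NMB(λ) > 0) over a
default grid of $0–60,000 in $500 steps; the value at $2,500/QALY is
reported but not asserted anywhere, since with mean-centred distributions a
high acceptability at $2,500 is not implied by a base-case ICER near
$21–24 k.

## Synthetic data

The generator emulates the real inputs with known ground truth: (a)
per-patient Weibull survival times by inverse transform,
T = unit·(−ln U/λ)^{1/γ}, with administrative censoring (default 168 days,
the 24-week treatment window; a 5-year horizon is used for survival-tail
work); arm sizes default to 23 (intervention) and 24 (comparator), the
trial's 47 enrolled patients. (b) Kaplan-Meier curves of those samples
(product-limit estimator via lifelines). (c) "Digitized" curve coordinates:
time positions uniform over the curve's support, step-function survival
read exactly, Gaussian jitter on the survival axis only (pixel-reading
error; default sd 0.02), clipped to (0, 1] and made non-increasing. (d)
Per-visit effect changes: specified means plus additive Gaussian noise
(defaults per metric on the scale of its typical change; no dispersion was
published, so these are generator defaults, not variance estimates).
Default non-QoL effect profiles are back-derived anchors — the between-arm
difference at each visit is ΔC_v / published ICER_v, assigned to the
intervention arm — so the synthetic secondary analysis echoes the published
table; quality-of-life changes come directly from the utility schedules.

What passing tests show: the pipeline is internally consistent and the
estimators behave as designed on data whose generating process matches the
model family exactly. They do not show robustness to real digitization
artifacts (axis misreads, monotone pixel drift), informative censoring, or
non-Weibull hazards.

## Numerical choices and known limitations

- Weibull fitting is unweighted OLS on ln(−ln S) vs ln t (curve
  coordinates, not event times; exact on noiseless Weibull input). Points
  with S outside (0,1) are dropped, not clamped. The scale estimate is an
  extrapolation of the fitted line to t = 1 time unit and carries the slope
  noise amplified by the mean log-time: at 500 patients/arm its median
  |relative error| through the full simulate→KM→digitize→fit pipeline is
  ~12 % (shape ~4 %), falling to ~7 % at 5,000.
- The per-cycle death probability is clamped below 1 by one ulp so the
  documented open interval survives float underflow of deep-tail survival.
- Monetary inputs are validated to cent precision on read and carried at
  full float precision; the trace conservation and telescoping identities
  hold to 1e−12.
- Exactly two health states; no tunnel states, no microsimulation, no EVPI,
  no correlated PSA sampling (no correlation structure is available).
- The published primary totals are reproduced only to within ~19 % even by
  the best convention in the scan — the residual is attributable to the
  unstated time unit and accrual details of the original implementation,
  not recoverable from the published parameters alone.
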