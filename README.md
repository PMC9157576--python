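# shpn-cea

A Markov cohort cost-effectiveness model of **supplemental home parenteral
nutrition (sHPN)** versus best-practice nutritional care for patients with
incurable gastrointestinal cancer, from the Chinese healthcare perspective.
It is aimed at health-economics analysts who want a scriptable, tested
re-implementation of this analysis — survival modelling, cost/QALY accrual,
primary and secondary ICERs, threshold analysis, and deterministic plus
probabilistic sensitivity analysis — with a synthetic-data generator
standing in for the underlying trial data.

## The model

A cohort moves between two states (survive, die) in 6-week cycles over a
5-year horizon. Overall survival per arm is Weibull,
S(t) = exp(−λ t^γ), so the death probability in the cycle ending at t is

    P(t) = 1 − exp(λ[(t − u)^γ − t^γ]) = 1 − S(t)/S(t − u),

with u the cycle length in model time units. Costs (one-time at model
start, or per-cycle while alive) and QALYs (alive × visit-wise utility ×
42/365.25) accrue per cycle and are discounted at 3 %/year by exact day
counts. Outcomes are the increments ΔC, ΔE between arms, the ICER = ΔC/ΔE
against a willingness-to-pay of $29,307/QALY (3× per-capita GDP), the net
monetary benefit λ·ΔE − ΔC, and the cost *headroom* — the largest extra
one-time intervention cost keeping the ICER at the threshold. Sensitivity
analyses follow the usual conventions: ±50 % (costs) and ±30 %
(utilities, Weibull parameters) one-way bands ranked in a tornado, and
1,000-iteration Monte Carlo with beta (utilities, transitions) and gamma
(costs) distributions feeding an acceptability curve. See
`docs/methods.md` for the full account.

## Worked example

The base-case parameter set (costs, utilities, Weibull parameters per arm)
ships with the package. The published survival parameters come without a
stated time unit, so the engine exposes it; the convention that best
reproduces the published totals is a 14-day unit with treatment-linked
costs stopping after the 24-week treatment window (4 cycles):

```sh
shpn-cea run --out out --time-unit-days 14 --treatment-cycles 4
```

prints

```
     arm         cost     qaly     d_cost   d_qaly         icer   dominance
    sHPN 10158.327404 0.723218 2647.25592 0.127366 20784.695307 tradeoff_NE
Non-sHPN  7511.071484 0.595852        NaN      NaN          NaN
ICER: 20,784.70 $/QALY (tradeoff_NE)
NMB at WTP 29,307: 1,085.45 $
```

Reading: the sHPN arm costs $10,158 and yields 0.723 QALYs per patient;
the comparator $7,511 and 0.596. sHPN costs $2,647 more and gains 0.127
QALYs (an ICER of $20,785/QALY, "tradeoff_NE" = dearer but more
effective). At the $29,307/QALY threshold the positive net monetary
benefit ($1,085) means sHPN is cost-effective under this convention.

Other commands: `shpn-cea secondary` (per-visit ICERs for quality of life,
BMI, fat-free mass, FFM index, handgrip, 6-minute walk), `shpn-cea dsa`
(tornado), `shpn-cea psa` (CE-plane cloud + acceptability curve),
`shpn-cea fit-survival km.csv` (Weibull from digitized Kaplan-Meier
points), `shpn-cea simulate` (synthetic trial data). All write plain CSV;
everything is also available as library functions (`shpn_cea.run_cea`,
`shpn_cea.run_psa`, ...).

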