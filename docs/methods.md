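# Methods

## Model structure

The simulator advances a weighted population of persons aged 18–64
through annual time steps from 2016 to a configurable horizon (default
2050). Within each year the event order is fixed: (1) every living
person faces a Bernoulli death draw; (2) survivors draw a next-year
tobacco-use state; (3) the state history shifts (current → prior) and
the years-since-quit counter updates; (4) ages increment by exactly one
year; (5) the year's cohort of 18-year-olds enters; (6) persons now
older than 64 leave the reporting population (recorded as aged-out, not
dead). Death-before-transition avoids transitioning the deceased; the
ordering is a modeling convention and all tallies account for it
exactly: start − deaths − aged-out + entrants = end weight holds to
machine precision in every replication year.

Sex, race group, poverty status and initiation-age category are fixed
at entry and never change. Age enters the transition models linearly in
years (no splines). The five-state space and its topology (never-smoking
is irreversible) are enforced structurally: the ever-smoker model simply
has no never-smoker destination, so forbidden transitions carry exactly
zero probability rather than a small one.

## Transition models

Two weighted multinomial logits with non-menthol smokers as the
reference destination define the second-order Markov kernel. The
ever-smoker model has 14 covariates per destination (intercept, four
state-at-j−2 dummies and three state-at-j−1 dummies — e-cigarette/dual
is the omitted reference of both history blocks — two initiation-age
dummies, race, age, sex, poverty) over destinations {former, menthol,
e-cig/dual}. The never-smoker model keeps the intercept and the six
demographic terms over destinations {never, former, menthol,
e-cig/dual}: every never smoker shares the same history, so history
dummies are not identifiable there. The never→former destination is
retained and read as "initiated and quit within one annual step"; it is
rare under the default dynamics (~0.1%/yr).

Estimation rows are sliding three-wave windows per person; each row
carries the person's longitudinal survey weight as a frequency-style
multiplier of the log-likelihood. Fitting is full Newton–Raphson with
step halving, converging when the gradient max-norm falls below 1e-8
(at mean-1 weight normalization; configurable, max 500 iterations).
Weights are normalized to mean 1 inside the optimizer: point estimates
are invariant to weight rescaling, and the inverse-Hessian standard
errors then reflect the number of observation rows rather than the
represented population. Two caveats are deliberate: sliding windows
from one person are treated as independent (no within-person
correlation correction), and the standard errors are naive weighted-MLE
errors, not design-based ones. Covariates without within-sample
variation are dropped with a report (their coefficients pinned at
zero); an outcome category absent from the data triggers a
reduced-destination fit with the missing destination's intercept set to
−30 (predicted probability effectively zero).

## Rate calibration

The calibration policy multiplies, in every simulated year from 2017
on, the never-smoker probabilities of entering any current-use state by
0.945 and the current-user probability of quitting by 1.055. Two
renormalization conventions had to be chosen: freed initiation mass is
returned to staying-never (rather than spread over all destinations),
and added cessation mass is removed proportionally from the non-quit
destinations. Never→former is not treated as initiation. The default
mode applies the same multipliers each year (an every-year constant
adjustment); a compounding mode (multiplier^k in the k-th adjustment
year) is available for sensitivity. A cessation-inflated quit
probability above 1 is clipped at 1 with the remaining mass set to 0.

## Mortality

Below age 55 the annual death probability is the age–sex life-table
value; three calendar regimes exist (2016, 2017, and 2018 applying to
2018 and all later years). From age 55, rates are status-specific:
r_status = r_never · RR_status with r_never = q / (prevalence-weighted
mean RR), so the prevalence-weighted average of the status rates
reproduces the life-table q exactly (verified to 1e-12 per cell).
Former-smoker RRs depend on years since quitting (bins <2, 2–4, 5–9,
10–19, 20–29, 30–39, 40–49, ≥50) and decline toward 1. Menthol and
non-menthol smokers share the current-smoker RR, as do e-cigarette/dual
users (their risk is therefore over-stated for exclusive e-cigarette
users — a known limitation kept for comparability). Any implied rate
above 1 is capped with a warning; conservation is then reported as
broken for that cell rather than silently re-solved.

Uncertainty draws sample each RR from the lognormal whose 2.5/97.5
quantiles match the fixture's 95% CI (lognormal is the standard choice
for relative risks; a degenerate CI returns the point value), then
repair monotonicity across years-quit bins by a running minimum and
floor at 1.

The years-quit counter starts at 1 in the first former-smoker year,
increments while the person stays former, and resets on relapse; a
fresh quit restarts at 1. For the initial population the counter is the
number of consecutive observed former waves; persons former in every
observed wave additionally get a pre-panel duration drawn from a
geometric distribution (mean 12 years total, capped at 60), since the
panel cannot identify long quit durations.

## Population dynamics and uncertainty design

The initial population takes each panel person's state at the reference
wave (default wave 3 = 2016) as current state, the preceding wave as
prior state, demographics from wave 1, and the panel weight unchanged.
Weight calibration applies the closed-form pair a = target·W/W_s,
b = (1−target)·W/W_n to smoker and non-smoker weights; "smoker" means
current cigarette smoker (menthol + non-menthol). E-cigarette/dual
users are counted as non-smokers for calibration because the benchmark
is cigarette prevalence; a flag can include them.

The uncertainty design crosses 20 sampled RR sets with 20 initial
population versions and 25 trajectory seeds (10,000 replications by
default; the test and acceptance runs use a 2×2×3 scaling). Population
versions are weighted bootstrap resamples — persons drawn with
probability proportional to weight, weights reset to total/n — chosen
because it preserves the total weight and person count exactly; the
variant prevalence is then a binomial share, which the tests use as an
oracle. Every random stream derives from
`SeedSequence(master_seed, spawn_key=(domain, *indices))`, so any
replication is reproducible in isolation, results are independent of
execution order, and interrupted experiments can resume bit-identically.

Entering cohorts add a fixed total weight (default 4.0 million) of
18-year-olds per year, split over a configurable number of equal-weight
synthetic entrants (default 200–500 depending on population size, so
entrant weights resemble existing ones); specs beyond the last
data-informed year reuse the final spec. Aged-out persons are removed
entirely rather than silently simulated, which leaves 18–64 outcomes
identical at lower cost.

Outcome aggregation reports weighted prevalences (percent) per year,
subgroup (US total, non-Hispanic Black, other race/ethnicities,
below/at-above FPL) and measure (five states, the cigarette aggregate,
menthol share among smokers). The 95% uncertainty interval is the
empirical 2.5th–97.5th percentile across replications with linear
interpolation between order statistics (the choice matters at small
replication counts). Display rounding is one decimal; files keep full
precision.

## Synthetic data generator

The generator stands in for a restricted-access longitudinal cohort and
its companion external sources, with defaults set to the magnitudes of
the 2014–2017 US adult population it emulates:

- wave-1 states at a weighted cigarette prevalence of 18.41% (total
  weight 189,584,407), tilted so smoking is 1.8× as common below the
  poverty line (ratio ≈ 2.1 below/above) and the menthol share among
  smokers is 85% for non-Hispanic Black persons vs ~32% for all others
  (38% overall);
- ground-truth transition coefficients chosen so one-year quit
  probabilities span roughly 4–60% across histories (long-term menthol
  smokers lowest, within-panel initiators highest), aggregate quitting
  runs near 8–9%/yr against initiation and relapse inflows, and overall
  prevalence declines about half a percentage point per year across
  waves — so the 2016 reference-wave prevalence sits near 17.5%;
- wave-1 ages 18–62 (so everyone is still ≤64 at the 2016 reference
  wave; the missing 18–19-year-olds are replenished by entering
  cohorts), a 49/51 sex split, 12% non-Hispanic Black, 15% below FPL;
- design weights lognormal (σ = 0.5) around equal shares, rescaled to
  the target total;
- a life table anchored at {18: 0.0009, …, 64: 0.019} (log-linearly
  interpolated, male ×1.25 / female ×0.76), whose crude rate over the
  reference population is ≈ 0.005/yr;
- current-smoker RRs of 2.5–2.9 at 55+ with ±12% multiplicative 95%
  CIs, and former-smoker RRs declining 2.3 → 1.0 across quit bins.

Wave 2 given wave 1 is drawn from a first-order approximation (the
prior state set equal to the wave-1 state) — a generator convention,
since a real panel simply observes both waves; waves 3+ use the full
second-order kernel. Never smokers carry no initiation age (a flag can
give a small fraction one, to exercise the drop-if-constant rule).

What the generator does *not* emulate: multi-stage sample designs,
nonresponse and attrition, item missingness, within-person correlation
beyond the second-order state dependence, product-market shocks (e.g.
the post-2017 e-cigarette surge), and immigration. Passing tests
therefore demonstrate internal correctness of estimation, calibration,
mortality accounting and the replication design — not that projections
from any particular real panel would be unbiased.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes chosen as the
package's own defaults: panels of 10,000–200,000 persons (parameter
recovery at 100,000; transition-frequency convergence at 200,000),
replication designs scaled to 2×2×3, and 5–35 simulated years.
Probability computations use max-subtracted softmax; log-likelihoods
use log-sum-exp and are finite for any finite logits; probability-
vector sums are exact to 1e-12 and the mortality conservation identity
to 1e-12. Categorical sampling is inverse-CDF on a single uniform per
person-year, making every draw a pure function of the generator state.

## Known limitations

Naive standard errors (see above); no design-based variance; no
youth states or non-cigarette combustibles; a single status-quo
scenario (no policy counterfactual machinery); calibration multipliers
are taken as given, not searched; and the e-cigarette/dual mortality
assignment over-states exclusive-vaper risk.
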