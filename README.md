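# tobaccosim

An individual-based (microsimulation) model of tobacco-use behavior in a
US-style adult population aged 18–64, for researchers who project smoking
prevalence, quantify income- and race-based disparities, and study how
menthol vs non-menthol cigarette use evolves under status-quo dynamics.

Each simulated person carries fixed demographics (age, sex, race/ethnicity
group, poverty status, smoking-initiation-age category), a survey weight,
and a two-year history of tobacco-use states drawn from five mutually
exclusive categories: never smoker (1), former smoker (2), menthol
cigarette smoker (3), non-menthol cigarette smoker (4), and
e-cigarette/dual user (5). Never-smoking is exited irreversibly.

## The model

Next-year states follow a **second-order Markov process**: the transition
distribution depends on the states in both of the two preceding years.
Transition probabilities come from two weighted multinomial logistic
regressions with non-menthol smokers (state 4) as reference. For a person
with an ever-smoker current state, the logit of destination *i* ∈ {2, 3, 5}
in year *j* is

    L_{j,i} = α_i + Σ_{k=1..4} β_{k,i} · I(state at j−2)
                  + Σ_{k=5..7} β_{k,i} · I(state at j−1)
                  + β_{8,i} I(init < 18) + β_{9,i} I(init ≥ 18)
                  + β_{10,i} I(race other) + β_{11,i} · age_{j−1}
                  + β_{12,i} I(male) + β_{13,i} I(below FPL)

and probabilities follow from p_{j,4} = 1 / (1 + Σ_i e^{L_{j,i}}),
p_{j,i} = p_{j,4} e^{L_{j,i}}. Current never smokers all share one history,
so their model (destinations *i* ∈ {1, 2, 3, 5}) uses an intercept and the
demographic terms only.

Around that core the simulator implements:

- **Mortality** — age–sex life-table rates below age 55; from 55 on,
  smoker-status-specific rates built from relative risks (current smokers,
  and former smokers by years-since-quit bin <2 … ≥50) that exactly
  conserve the life-table average in every age–sex cell. E-cigarette/dual
  users carry the current-smoker risk; menthol and non-menthol smokers
  share one risk.
- **Weight calibration** — closed-form reweighting of smokers vs
  non-smokers so the initial weighted cigarette prevalence matches an
  external benchmark (18.41% under panel weights → 15.13%) while
  conserving the total weight exactly.
- **Rate calibration** — annual multipliers 0.945 on never-smoker
  initiation and 1.055 on current-user cessation.
- **Population dynamics** — an entering cohort of 18-year-olds each year
  and retirement of persons over 64.
- **Uncertainty** — a crossed design of 20 relative-risk draws × 20
  bootstrap initial populations × 25 trajectory seeds (10,000
  replications); reported intervals are empirical 2.5th–97.5th percentile
  ranges across replications.

A synthetic-data module generates every input the original analysis drew
from restricted or external sources — a weighted 4-wave longitudinal
panel with known ground-truth coefficients, life tables, relative-risk
and smoker-status-prevalence fixtures, benchmark prevalence series, and
entering-cohort specifications — so the whole pipeline is testable by
parameter recovery and self-consistency.

## Worked example

```python
import tobaccosim as ts
from tobaccosim.states import TobaccoState

coeffs = ts.default_ground_truth().coefficients
ctx = ts.TransitionContext(
    age=45, male=True, race_other=True, init_age_cat="lt18", below_fpl=False,
    state_prior=TobaccoState.MENTHOL, state_current=TobaccoState.MENTHOL, year=2020,
)
probs = ts.compute_probabilities(ctx, coeffs)
calibrated = ts.apply_calibration(probs, ctx, ts.CalibrationPolicy())
```

prints (see `examples/03_transition_probabilities.py`):

```
45-year-old male long-term menthol smoker, next-year probabilities:
  -> FORMER       6.15%
  -> MENTHOL     84.94%
  -> NONMENTHOL   7.33%
  -> ECIG_DUAL    1.57%
quit probability before/after cessation calibration: 6.15% -> 6.49%
```

The person most likely remains a menthol smoker; the 1.055 cessation
multiplier raises his quit probability by 5.5% and the remaining
destinations shrink proportionally. A small full projection run
(`examples/05_projection_experiment.py`, 8 replications, 2016–2030):

```
  2016: cigarette prevalence 15.7% (95% UI 15.2-16.1)
  2030: cigarette prevalence 11.7% (95% UI 11.3-12.0)
  2030 below_fpl: 20.0% (19.5-20.5)
  2030 at_above_fpl: 10.1% (9.8-10.5)
```

— prevalence declines under status-quo dynamics while the below-poverty
rate stays roughly twice the at/above-poverty rate.

The `examples/` directory holds one short script per capability (panel
generation, model estimation, transition probabilities, the mortality
adjustment, and a projection experiment). A thin CLI mirrors the shell
workflow: `tobaccosim generate`, `tobaccosim estimate`,
`tobaccosim simulate --config run.yaml --out results/`.

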