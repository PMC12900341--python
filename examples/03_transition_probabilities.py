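"""Per-person transition probabilities and the annual rate calibration.

Probabilities come from the fitted logits via p_ref = 1/(1 + sum e^L)
with NONMENTHOL as reference; the calibration then lowers never-smoker
initiation by 5.5% and raises current-user quitting by 5.5% each year.
"""

import tobaccosim as ts
from tobaccosim.states import TobaccoState

coeffs = ts.default_ground_truth().coefficients

ctx = ts.TransitionContext(
    age=45, male=True, race_other=True, init_age_cat="lt18", below_fpl=False,
    state_prior=TobaccoState.MENTHOL, state_current=TobaccoState.MENTHOL, year=2020,
)
probs = ts.compute_probabilities(ctx, coeffs)
print("45-year-old male long-term menthol smoker, next-year probabilities:")
for s, p in probs.items():
    print(f"  -> {s.name:<10} {100 * p:6.2f}%")

calibrated = ts.apply_calibration(probs, ctx, ts.CalibrationPolicy())
print(f"quit probability before/after cessation calibration: "
      f"{100 * probs[TobaccoState.FORMER]:.2f}% -> "
      f"{100 * calibrated[TobaccoState.FORMER]:.2f}%")
print(f"vector still sums to {sum(calibrated.values()):.12f}")

# The 1.055 cessation multiplier raises the quit probability by 5.5%;
# the other destinations shrink proportionally so the vector stays a
# probability distribution. Transitions back to never-smoking carry
# exactly zero probability.
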