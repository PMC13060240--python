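"""Fit a developmental trajectory and locate significant change windows.

A penalized-spline mixed model (cubic shrinkage basis, k=5, REML) with
subject random intercepts and slopes is fitted to the firing-rate
outcome; the trajectory is predicted on the fixed 100-point maturation
grid and a simultaneous 95% band on its finite-difference derivative
flags the aligned-age windows of significant developmental change.
"""

from trajalign import (
    CohortConfig,
    derivative_windows,
    fit_smooth,
    gen_cohort,
    predict_grid,
)
from trajalign.cohort import firing_rate_spec

config = CohortConfig(seed=2, outcome_specs=[firing_rate_spec()])
_, dataset = gen_cohort(config)

fit = fit_smooth(dataset, "firing_rate", k=5)
print(fit.summary(), "\n")

ages = dataset.subset("firing_rate")["aligned_age_months"]
curve = predict_grid(fit, float(ages.min()), float(ages.max()), n_grid=100)
print(f"fitted minimum {curve.values.min():.2f} spk/s at aligned {curve.argmin_age:.1f} mo")
print(f"fitted maximum {curve.values.max():.2f} spk/s at aligned {curve.argmax_age:.1f} mo")

windows = derivative_windows(fit, curve, n_sim=10_000, alpha=0.05, seed=0)
for start, end, sign in windows.intervals:
    direction = "increase" if sign > 0 else "decrease"
    print(f"significant {direction} from aligned {start:.1f} to {end:.1f} months")
print("\nwindows are where the simultaneous 95% derivative band excludes 0:")
print("firing rate rises through early adolescence, then the band widens")
print("and the plateau is no longer a significant change.")
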