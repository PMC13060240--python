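# Methods

## Marker alignment

Each subject carries one maturation-marker age (months); aligned age is
chronological age minus marker age, so 0 is the maturation event for
every subject. Alignment is a per-subject translation — a bijection —
and a missing marker is an error, never imputed. All ages are carried
in months internally; years convert at exactly 12.

Session-level behavioral performance is percent of correct trials.
Where the similarity analysis needs one behavioral reference curve, the
three task variants are pooled per session by combining their trials
(the variants' trajectories are nearly perfectly correlated, so pooling
loses essentially no shape information); per-variant analyses remain
available by fitting each variant's rows separately.

Time-point comparisons use the Mann-Whitney U test. For combined
samples of at most 16 the two-sided p-value is computed by exhaustive
enumeration of group assignments (exact under ties; the two-sided
criterion is |U − n₁n₂/2| at least the observed distance). Larger
samples use the tie-corrected normal approximation with continuity
correction; if the tie-corrected variance is zero (all pooled values
identical) p = 1 by contract.

## Trajectory model

For one outcome, observations y_ij of subject i at aligned age t_ij:

    y_ij = α + f(t_ij) + a_i + b_i t_ij + ε_ij

* f is a natural cubic regression spline with k = 5 basis functions
  (knots at evenly spaced quantiles of the observed aligned ages),
  centered by a sum-to-zero constraint so the intercept is identified,
  and penalized by the integrated squared second derivative plus a
  small ridge (1e-6 × trace of the penalty) on the penalty null space.
  The ridge makes the basis a *shrinkage* basis: as λ → ∞ the smooth
  collapses to zero rather than to an unpenalized line. With λ fixed at
  0 and random effects disabled, the fit reduces exactly to the
  unpenalized least-squares regression spline (tested against an
  independent `lstsq` oracle).
* (a_i, b_i) are subject random intercepts and slopes on aligned age,
  with independent variances. If REML with random slopes fails to
  converge the model falls back to intercept-only random effects with a
  recorded warning.
* Estimation: the fixed/spline coefficients are profiled analytically;
  the REML criterion (n−1)·log(penalized RSS) + log|A| − log|P| is
  minimized over (log λ, log variance ratios) by bounded L-BFGS-B, with
  a Nelder-Mead polish when the quasi-Newton line search fails at a
  variance-component bound (this happens when a variance is effectively
  zero). The response is standardized internally so the selected
  parameters — and hence the fit — are exactly equivariant under affine
  maps of y.
* Uncertainty: the Bayesian posterior covariance V = σ̂²(M'M + P)⁻¹
  gives pointwise 95% bands on the population curve (random effects set
  to zero). Average across-the-function coverage on simulated smooth
  truths is close to nominal (≈ 93–95% in the test suite's 500-replicate
  check); pointwise coverage dips where the penalty biases the fit, the
  usual behavior of penalized-spline bands.
* A Wald-type chi-square test of the spline coefficients provides the
  per-outcome p-value entering FDR correction across outcomes. This is
  a convention choice — the test statistic entering the FDR step is not
  otherwise pinned down — and is labelled as such in reports.

Predictions are made on a fixed, evenly spaced 100-point grid. In the
pipeline the grid bounds are the earliest and latest *behavioral*
aligned ages, shared by all outcomes so curves are comparable;
extrapolation beyond an outcome's own data range is permitted but
flagged with a warning.

## Derivative change windows

The curve derivative is approximated by central finite differences on
the grid (one-sided at the ends), with step equal to the grid spacing.
The derivative is linear in the coefficients, d = L·β, so a
simultaneous (1−α) band is calibrated by simulating coefficient draws
from N(β̂, V), computing the maximum over the grid of the standardized
deviation |L(β* − β̂)|/sd, and taking its (1−α) quantile as the critical
multiplier (default 10,000 draws; fewer than 100 is rejected).
Windows are maximal runs of grid points where the band excludes zero,
reported with the derivative's sign; the reported sign always matches
the numerical slope of the fitted curve inside the window. Under a flat
truth the flagged fraction of the grid stays below α (measured ≈ 0.02
at α = 0.05 in 500-replicate calibration).

## Similarity statistics

Curves are z-scored with the sample SD (divisor n−1); the divisor
cancels in r and only rescales the folded RMSE uniformly. Folding is
baseline shift (subtract the first grid value) followed by absolute
value, so oppositely signed but congruent trajectories fold onto the
same non-negative shape; RMSE is then the root mean square of
elementwise differences of the folded curves. r is computed on the
z-scored (unfolded) curves and retains sign.

The maxT permutation test shuffles the grid indices of each pair's
second curve independently in every permutation (shuffling one member
is distributionally equivalent to shuffling both under exchangeability)
and uses the family maximum of |r| as the reference statistic;
p = (1 + #{T_b ≥ |r_obs|})/(n_perm + 1), so the smallest attainable p
is 1/(n_perm+1), and by construction the maxT p dominates the per-pair
unadjusted p. The family is whatever set of pairs is passed in one
call; the pipeline uses one family per tract metric (all FA tracts vs
behavior; all RD tracts vs behavior).

**Known limitation.** Index permutation destroys the autocorrelation of
smooth fitted curves, so the null is anti-conservative for them:
p-values for smooth trajectories are best read as a family-calibrated
ranking, not exact error rates. The pipeline prints this caveat into
`summary.json`. The family-wise error calibration in the test suite
therefore uses white-noise curves, where the null is exchangeable and
the measured FWER at α = 0.05 is ≈ 0.05.

## Synthetic cohort generator

The generator emulates the study conditions the analyses assume:

* 4 subjects, visits every 3 months from 34 to 75 months of age;
  marker ages ~ Normal(57.9, 3.6²) months.
* Latent maturation curves are 4-parameter logistics on aligned age
  (lower/upper asymptote, midpoint, slope), chosen because the
  behavioral narrative is steep early-adolescent gains followed by a
  plateau. Defaults: antisaccade probability 0.40 → 0.90 with midpoint
  −10 aligned months and slope 6; firing rate 10 → 25 spk/s (midpoint
  −5, slope 8); FA tracts rise by 0.12 from per-tract baselines
  0.35–0.47, RD tracts mirror them downward, with per-tract midpoints
  −13 to −7 and slopes 5–8 so tracts mature on slightly different
  schedules.
* Behavior is generated per session (19 sessions per visit, 72 trials
  per variant per session) as Binomial counts at the latent probability
  shifted per variant on the logit scale (+0.4 overlap / 0 zero-gap /
  −0.4 gap — the difficulty ordering is known, the magnitudes are a
  design choice) plus subject effects on the probability scale;
  probabilities pushed outside [0,1] are clamped and counted, with the
  count logged and stored in the dataset metadata.
* Gaussian families add subject random intercept + slope (on aligned
  age, matching the fitted model) and Normal noise; random-effect SDs
  default to a few percent of each outcome's dynamic range
  (e.g. 0.5 spk/s intercept SD for firing rate), realistic for
  between-animal baseline differences without swamping the shared
  maturation signal.
* Each outcome's RNG stream is seeded by a stable hash of
  (seed, outcome name): identical configs are byte-reproducible and
  adding outcomes never perturbs existing ones.

What the generator does **not** emulate: trial-by-trial eye movements,
spike trains, image-level diffusion data, visit-schedule irregularities,
missing visits, or outcome-specific observation schedules (all outcomes
share one visit grid). Passing tests on this generator therefore
demonstrates the statistical machinery's correctness and calibration
under the assumed data-generating process, not robustness to the messier
features of real longitudinal animal data.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 100 seeded cohorts for
latent-curve recovery (pass criterion: curve RMSE < 5% of dynamic range
on the 100-point grid), 500 replicates for derivative-band null
calibration (1,000 posterior draws each), a single high-n run for band
power, and 500 simulated families (n_perm = 200, 5 pairs) for maxT
family-wise error — sizes chosen to keep Monte-Carlo error a small
fraction of the margins being checked while the whole suite runs in
well under a minute per study. REML convergence tolerance is ftol
1e-11 on the profiled criterion with bounds log λ ∈ [−12, 20] and log
variance ratios ∈ [−12, 8]; the optimizer landing on a bound is
equivalent to switching the component off. Degenerate inputs are
contracts, not crashes: constant outcomes fit as exact constants with
zero derivative and no windows, but z-scoring a constant curve raises,
since similarity of flat curves is undefined.
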