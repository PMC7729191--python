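# Methods

This note records the models implemented in `facekin`, the defaults chosen
where the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## Shape normalization

All frames of all clips of a study are pooled into a single Generalized
Procrustes superimposition.  Each configuration is translated to a zero
centroid and scaled to unit centroid size (root sum of squared centered
coordinates); with rotation enabled (the default) each is then rotated to
minimize squared distance to an iteratively refined consensus, using the 2-D
closed-form rotation angle.  Iteration stops when the consensus changes by
less than `tolerance` (default 1e-8, measured as rotation-invariant
Procrustes RMSD of successive consensuses) or after `max_iterations`
(default 100); non-convergence raises a warning, not an error, and the
partially converged alignment is returned.  Convergence is geometric; dense
face-like data converges in a handful of iterations, while highly dispersed
shape sets (e.g., unstructured random configurations) may need several
hundred, which is why the tests raise the cap where they use such inputs.

Pooling all clips (rather than aligning each clip separately) is deliberate:
baseline faces extracted from different clips must live in the same
coordinate frame for cross-clip RMSDs to be commensurable.  Reflections are
excluded by default because faces have handedness.  The final consensus is
canonicalized — principal axis rotated onto +x, sign fixed by the first
landmark — so the output frame does not depend on the orientation or order
of the inputs; aligned coordinates are dimensionless.

## Kinematic measures

For a normalized $T$-frame clip with $N$ landmarks:

* distance series (length $T$): RMSD of each frame to a baseline face;
* speed series (length $T-1$): RMSD between consecutive frames, i.e. RMS
  per-landmark speed with a one-frame interval, in units per frame;
* acceleration series (length $T-2$): RMS magnitude of the per-landmark
  finite-difference acceleration vectors, units per frame².

The acceleration definition divides the velocity difference by the two-frame
span it covers.  A plausible alternative convention skips that division
(treating the raw difference of consecutive velocity vectors as the
acceleration); `accel_denominator=1` exposes it, and the two differ only by
the constant factor 2, which is irrelevant to any correlation-based result.

Each series is aggregated over its own support by mean and maximum; series
of different lengths are never padded.  Baselines are taken *after*
normalization — a raw-pixel first frame would not be commensurable with
normalized frames.  The actor mean face pools all frames of all the actor's
clips, so longer clips carry proportionally more weight.  Time units are
frames throughout; none of the correlational results depend on the frame
rate because predictors are z-scored before modelling.

## Measure selection

The 8×8 Pearson matrix of the candidate measures is partitioned into blocks
by connected components of the graph joining measures with $|r| \ge 0.5$
(configurable).  The threshold matches the "moderate to strong" reading of
within-block correlations; selection requires at least two blocks and
defaults to the mean-aggregated distance-to-neutral and speed measures —
mean aggregation is more robust to single-frame tracking glitches than the
maximum.  No multiplicity correction is applied to this exploratory matrix.

## Rating models

Ratings (integers 1–101 on a visual-analog scale) are averaged per clip
within each rater group; clips unrated in a group are dropped, which is
unbiased because raters are assigned to clips completely at random.  OLS
models with t-based 95% CIs are fitted via statsmodels:

* within group: mean arousal on z-scored distance and speed (z-scored over
  the analysis clips, not any larger pool);
* between groups: the per-clip difference of group means on the same
  predictors — the intercept measures a mean rating offset;
* single-predictor and valence-response variants of both.

Standardized coefficients are the estimates of the model with the response
additionally z-scored; they are obtained by exact linear rescaling of the
fitted model, which equals a literal refit (verified in tests).  Leverage is
the hat-matrix diagonal (mean $k/n$ by the trace identity).  The outlier
rule flags clips whose value on the distance measure lies more than 4
leave-one-out standard deviations from the leave-one-out mean; the
reference analysis identified such clips visually in added-variable plots,
so the numeric rule is an explicit, configurable approximation, and re-fits
with flagged clips removed are reported alongside the full fits.
Added-variable data are the residual pairs from regressing response and
focal predictor on the remaining predictors; their OLS slope equals the
full-model coefficient (Frisch–Waugh), which the tests assert to 1e-10.

Degenerate inputs: a constant response makes R² and F undefined and they are
reported as NaN (not clamped); zero-variance predictors and rank-deficient
designs are rejected with the offending columns named.

## Synthetic data generator

The generator emulates short acted-expression clips and the two-panel rating
design the models assume.

**Clips.** A deterministic 68-landmark template face (jaw, brows, nose,
eyes, lips in the standard layout, small seeded jitter, centroid 0, size 1)
is displaced along a smooth random per-landmark field.  The field is
projected orthogonal to the similarity transforms of the template and scaled
to unit RMS, so the amplitude parameter $A$ *is* the peak RMSD from the
neutral first frame; the raised-cosine envelope
$g(f) = (1-\cos(2\pi f/(T-1)))/2$ makes each clip neutral → peak → neutral.
With no noise and no nuisance transforms the distance-to-neutral series
equals $A\,g(f)$ exactly (mean over the $T$ frames: $A\,(T-1)/2T$), the mean
speed is $2A/(T-1)$, and these closed forms are the oracles for the
kinematics tests.  Per-frame nuisance translation/scale/rotation jitter
(defaults 0.02 in consensus units / log-scale / radians) and i.i.d.
coordinate noise (default 2e-5) emulate camera and tracker imperfections;
the normalization removes the similarity jitter exactly.

**Amplitude–duration structure.** Mean distance scales with $A$ and mean
speed with $A/(T-1)$, so the distance–speed correlation across clips is
controlled by drawing $(\log A, \log(T-1))$ bivariate normal: the log-scale
correlation is solved in closed form (numerically inverted) from the
requested level-scale target, default 0.51 — the predictor collinearity the
rating models must cope with.  Defaults: $A$ lognormal with median 0.02 and
log-SD 0.4 (peak displacement a modest fraction of the face scale,
$1/\sqrt{68}\approx0.12$ per landmark); $T$ lognormal with median 100 frames
and log-SD 0.6.  The duration spread must exceed the amplitude spread for
low correlation targets to be attainable; with a fixed clip length the mean
speed would be exactly proportional to $A$ and the correlation untunable.

**Ratings.** Arousal per rating is the linear model on the z-scored measured
features, $\beta_0 + \beta_1 z(\text{dist}) + \beta_2 z(\text{speed})$, plus
a per-clip effect shared by all raters (SD 19 — unmodelled clip-level
appeal, identical across groups) and independent rater noise (SD 20), then
rounded and truncated to 1–101.  With these defaults the within-group models
see residual scatter near 20 rating points and the between-group difference
near 12 (the shared clip effect cancels in the difference).  Default
coefficients: NT intercept 47.60, distance slope 5.93, speed slope 2.53;
the ASD panel shares the slopes with the intercept lowered by 4.29 (HAT by
4.64).  Panels: 401 NT raters with 1–6 clips each (uniform — only the range
and the average rater load of the emulated design are known, not the exact
distribution), 19 ASD × 14 clips (hence 19·14/80 = 3.325 raters per clip),
41 HAT × 14.  Valence is generated independently of the kinematics (mean
51), encoding a null specificity relation as the generator's truth.
Ratings are generated from the *measured* (post-normalization) features, so
the generating coefficients are the exact estimands of the fitted models —
this is what makes the CI-coverage benchmark a sharp test.

**What the generator does not emulate:** photorealistic appearance,
emotion-category-specific dynamics, out-of-plane head rotation and
perspective artifacts, tracker dropouts, rater-specific response styles, or
informative missingness.  Passing tests therefore show that the pipeline's
statistics behave correctly under the assumed data-generating structure,
not that real videos satisfy that structure.

## Problem sizes and numerical choices

The test suite and the acceptance script use 80-clip studies (~100-frame,
68-landmark clips), 100-replicate coverage benchmarks, and 500-clip sets for
correlation calibration — sizes at which the pooled superimposition and the
OLS fits are exact enough for the stated tolerances and the whole suite runs
in seconds.  Exact-moment regression constructs (orthonormalized random
bases scaled to unit sample SD) are used wherever an analytic value is
asserted, so those checks are sharp to 1e-12 rather than Monte-Carlo loose.
CI-coverage assertions use a ≥88/100 criterion, the two-sided binomial
slack around a nominal 95% rate.

## Known limitations

* The VAS truncation at 1 and 101 slightly compresses group differences
  (the recovered between-group intercept averages a few percent below the
  generating offset) — an inherent property of bounded rating scales, left
  visible rather than corrected.
* Level-scale correlations of lognormal features converge slowly; realized
  correlations at n = 80 clips scatter roughly ±0.1 around the calibrated
  0.51, matching the uncertainty such a study design actually has.
* The outlier rule is univariate on the distance measure; it is a stand-in
  for visual inspection, not a general influence diagnostic (use the hat
  values and added-variable data for that).
* Only 2-D landmark input is supported; head-pose decomposition and
  region-restricted measures are out of scope.
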