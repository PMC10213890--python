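# Methods

`swayintensity` analyzes how well two remote-assessment proxies — participant
self-ratings and trunk-sway posturography — approximate expert physical
therapist (PT) ratings of standing balance exercise intensity on an ordinal
1–5 scale (1 = completely steady, 5 = loss of balance). Because the kind of
raw data it targets (per-trial lumbar-IMU sway angles plus crossed PT/self
rating tables) is rarely shareable, the package ships a synthetic-study
generator with fully known ground truth; every estimator is validated by
parameter recovery against that truth.

## The emulated study protocol

The default generator reproduces a protocol of 10 balance participants
(6 older adults, 4 with vestibular dysfunction), each performing 15 static
standing exercises for three 30-second trials (22.5 active minutes per
participant, 450 trials in total), with trunk sway recorded at 100 Hz.
Exercises are drawn from a factor space of surface (firm/foam) x stance
(feet apart ... single leg) x vision (open/closed) x head movement
(none/moving), with five excessively difficult code combinations excluded
(single-leg on foam; single-leg, eyes closed, head moving). Each
participant's 15 exercises are sampled one per difficulty stratum so every
participant spans the intensity range. Each participant is scored by 3–5 PT
raters drawn from a pool of 8; raters give per-trial and per-exercise
ratings, as does the participant (self-ratings).

## Synthetic sway

Each trial's AP (pitch) and ML (roll) angle series is Gaussian white noise
shaped by a 2nd-order Butterworth low-pass at the profile bandwidth
(default 1 Hz), demeaned, and rescaled so each axis's RMS equals its target
exactly. Target AP RMS grows geometrically from 0.3 deg (easiest) to 2.5 deg
(hardest exercise): sway amplitude varies multiplicatively across task
difficulty, so equal difficulty steps multiply sway, which also makes
log-transformed features the better linear correlates of intensity — the
pattern expected from the posturography literature. ML targets are 0.7 x AP.

What this emulates: stationary, band-limited sway whose magnitude tracks
difficulty, with exactly known RMS and simulable velocity/path/area truth.
What it does not emulate: non-stationarity within a trial (drift, stepping
events, harness/handrail use), heavy-tailed excursions near loss of balance,
axis coupling, or sensor noise and sensor-fusion artifacts. Passing tests
therefore certify the *estimators*, not the realism of any specific clinical
population's sway.

## Kinematic features

Series are zero-phase filtered (forward–backward 2nd-order Butterworth,
3 Hz cutoff; effective amplitude response is the single-pass magnitude
squared, so 0.5 at the cutoff). Both axes are demeaned before feature
computation. The eight features:

- `ap_rms`, `ml_rms` — RMS of the demeaned axis (deg); `phi_rms` with
  phi^2 = ap^2 + ml^2, so `phi_rms^2 = ap_rms^2 + ml_rms^2` exactly.
- `ap_mv`, `ml_mv` — mean |first difference| x sample rate (deg/s);
  `phi_mv` — mean planar step length x rate, so `phi_mv x span =
  path_length` exactly (span = (n-1)/fs).
- `path_length` — cumulative planar distance (deg).
- `elliptical_area` — pi * q * sqrt(lambda1*lambda2) from the eigenvalues of
  the 2x2 sample covariance of the demeaned (ML, AP) scatter, q the
  chi-square(2) quantile at the coverage (default 0.95). No small-sample F
  correction: at 3,000 samples per trial it is negligible. Rank-deficient
  scatter yields area 0.

Natural logs of all eight are carried alongside; a log of a zero feature is
flagged undefined (NaN + listed in `log_undefined`) rather than epsilon-
substituted, and analyses exclude such rows with a logged count. The two
exact identities double as internal cross-checks and are property-tested.

Conventions the original-style analysis leaves open — demeaning before RMS,
planar versus combined-axis mean velocity — are fixed as above and
configurable where it matters (coverage, cutoff, order).

## Ratings: latent-threshold model

Ratings come from a cumulative-ordinal model on a latent intensity that
already lives on the 1–5 scale (thresholds default to 1.5, 2.5, 3.5, 4.5).
The per-trial PT latent is

    intercept + w . difficulty_codes + b_participant + b_exercise
    + b_rater + b_trial(p,e,t) + noise,

with independent Gaussian components (defaults: sd 0.5, 0.25, 0.3, 0.35,
0.45 respectively; difficulty weights 0.366, 0.607, 0.584, −0.337 reproduce
the qualitative ordering that stance and vision matter most while head
movement is mildly protective in a mostly non-vestibular sample; the
intercept 0.25 centers the mean latent near 3). The trial draw is shared
across raters — it is the trial's actual performance. Self-ratings replace
the rater draw with a negative latent offset (people under-rate their own
instability) and multiply the trial-varying part (trial draw and noise) by
0.5, encoding that self-ratings vary less across a given exercise's trials.
Per-exercise latents are the mean of the rater's three per-trial latents.
Ratings are the latent discretized at the thresholds; the exact latent is
kept on every record so estimators can be tested against truth.

`calibrate_self_offset` bisects the offset so the *discretized* mean
PT − self difference hits a target (0.35 by default usage): thresholding
attenuates a latent shift because mass piles up at ratings 1 and 5, so the
calibrated latent offset (≈ −0.33) differs from the target difference.

## Inter-rater reliability

Per-trial PT ratings are decomposed by a linear mixed model with fixed
intercept and trial number and a random effect for every main effect and
interaction among trial, exercise, participant and rater (15 terms; terms
observed once per level — the four-way interaction here — are aliased with
the residual and dropped with a notice). The agreement ICC is

    ICC = 1 − (rater-involving variance + residual) / total variance,

the crossed-design analogue of ICC(2,1) for absolute agreement of single
ratings; the complementary literal ratio is reported alongside. Bands:
< 0.5 poor, [0.5, 0.75) moderate, [0.75, 0.9) good, >= 0.9 excellent
(left-closed boundaries). The per-exercise model drops all trial terms.

Two estimators: a profiled-REML fitter for arbitrary (unbalanced) designs —
variance ratios optimized by L-BFGS-B under nonnegativity, likelihoods via
the Woodbury identity on sparse indicator matrices, so cost scales with the
number of random-effect levels — and a closed-form expected-mean-squares
(ANOVA) estimator for balanced fully crossed designs, which also serves as
the independent oracle for the REML path (agreement to 1e-4 per component on
balanced data; statsmodels MixedLM agrees on small crossed designs).

Recovery note: the recovery simulations fit the *latent* (continuous)
ratings, where the generative variance fractions are defined; a true shared
fraction of 0.868 is recovered to within 0.03 in the mean over 200 studies.
Discretizing to 5 ordinal categories attenuates the observed-rating ICC to
roughly 0.79 under the same truth — a known property of coarse ordinal
scales, and the reason reliability of real ordinal ratings should be read as
a lower bound on latent-scale agreement.

## Associations

- Difficulty regressions: rating ~ one coded difficulty dimension with
  crossed random intercepts for participant and rater (fitted by the same
  REML engine); Wald 95% CI and normal p-value for the slope. One dimension
  at a time by default, matching the stated model form.
- Feature–rating correlation: rating ~ feature + (1 | participant) via
  statsmodels MixedLM (REML). The marginal correlation is
  R^2 = s2_f / (s2_f + s2_alpha + s2_eps) with s2_f = var(beta*x) computed
  as the population variance of the fitted fixed-effect contribution over
  the analyzed rows; r carries the slope's sign. This is invariant to affine
  rescaling of the feature and reduces to the Pearson correlation when the
  participant variance is zero.
- Spearman rho with average ranks for ties; Fisher-z 95% CI; t-approximation
  p-value. Per-exercise PT–self pairing joins the single self-rating to each
  of that participant's PT raters, using every PT rating.

Mixed-model p-values use the Wald normal approximation throughout; matching
any particular software's finite-sample p-values is not attempted.

## Agreement and prediction

Differences are PT − other. The mean difference's CI/p comes from an
intercept-only mixed model with random intercepts for participant and rater
(pairs sharing either are not independent). Trial-to-trial variance is
compared by a paired t-test across (participant, exercise) cells: self
variance across the three trials versus the PT variance per rater averaged
over raters. Predictions are OLS fits of PT ratings on either the paired
self-rating or the kinematic feature vectors (per-trial: the trial's 8 log
features by default; per-exercise: the three trials' vectors concatenated in
trial order, with a trial-mean option), rounded half-away-from-zero and
clipped to [1, 5]; accuracy is the exact-match fraction against individual
PT ratings, in-sample by default with a k-fold option. The rounding rule is
exposed because accuracy depends on it. Log phi-velocity and log path length
differ by a constant (the exact identity above), so the log predictor set is
rank-deficient by one; least squares uses the minimum-norm solution and
warns.

## Pipeline and reproducibility

One root seed feeds independent per-stage streams (design, sway, ratings);
identical configuration and seed reproduce the report byte for byte (floats
rounded to 10 decimals in the report to absorb last-ulp noise). Stages run
in dependency order — PT-rating evaluation first, then the comparisons — and
a stage failure aborts with a stage-named error after persisting completed
sections. Ratings are treated as continuous in all parametric analyses.
Intermediates (dataset CSVs, feature table, contingency tables, report JSON)
are plain text; sway series are written with `%.17g` and read back with
round-trip float parsing so datasets survive a write/read cycle bit-exactly.

Problem sizes: the full-study per-trial REML decomposition (n ≈ 1,900
ratings, ≈ 2,800 random-effect levels) takes on the order of two minutes;
the test suite exercises the same code paths on smaller designs and uses the
closed-form ANOVA path for the 200-study recovery loops.

## Known limitations

- The generator's sway is stationary and Gaussian; real near-fall trials are
  neither. Kinematics-based prediction accuracy on real data will differ.
- Ordinal discretization attenuates variance-ratio statistics (see above);
  all recovery claims are latent-scale claims.
- The self-rating model encodes one mechanism (constant latent offset,
  shrunken trial variation); real self-assessment biases are richer
  (memory, anchoring, scale misuse).
- REML p-values/CIs are Wald-based; no Satterthwaite or bootstrap degrees of
  freedom.
- Exercise difficulty enters the latent linearly in the coded levels; the
  codes are ordinal in reality.
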