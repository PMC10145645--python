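# Methods

## Input model and preprocessing

The pipeline consumes fixation *events* (participant, trial, onset, duration,
x, y) as exported by eye-tracker software; event detection itself is out of
scope. Areas of interest are the 9 matrix cells and 8 answer-choice
rectangles of a matrix-reasoning display, half-open `[x0, x1) × [y0, y1)` in
screen pixels so that every point receives exactly one tag. The bundled
default layout is a plausible stand-in for a Raven-style display (matrix
left, 2 × 4 answer bank right), not a reconstruction of any particular
stimulus set.

Per trial, filtering applies three rules in a fixed order: the first raw
fixation is dropped unconditionally (it carries over from the inter-trial
fixation point), off-AOI fixations are discarded, and only fixations of at
least 100 ms are kept. The threshold is inclusive (`>= 100 ms`) because
recorders with a 100 ms minimum emit boundary events exactly at the floor; a
`strict_threshold` flag switches to `>`. Filtering is idempotent once the
first-fixation rule is disabled.

Participant-level quality control excludes a participant when any rule
fires: validity ratio below 0.5 (fraction of trials with a non-empty filtered
scanpath, or an externally supplied tracking ratio), a mean below 3
fixations per trial ("two or fewer"), or any score further than 3 SD from
the cohort mean. The score rule is evaluated per column on the cohort that
survives the gaze rules, and a zero-spread column excludes nobody. The
denominator of the validity ratio is an interpretation choice (trials, not
raw samples); both the threshold and the interpretation are exposed as
options rather than asserted as facts about any particular dataset.

## The 14 gaze metrics

Aggregation follows a "totals convention" chosen to make the metric
definitions mutually consistent: transition and fixation counts are totals
over the scored trials; time-type quantities (item time, latency, fixation
durations) are per-trial or per-fixation means; visit metrics are means per
cell (9) or per wrong choice (7) per trial; the dwell ratio is total matrix
dwell over total answer dwell. Under this convention the transition-rate
metric satisfies `rate = n_ma / (avg_item_time_s × n_trials)` exactly (to
1e-9 in tests). Transitions are counted on the *collapsed* sequence
(consecutive same-AOI fixations merged), the same representation the
clustering uses; a "visit" is one maximal run, equivalently one collapsed
element. Trial duration is the offset of the last retained fixation —
response timestamps are not part of the input contract, so this approximates
the recorder's trial time. Degenerate denominators (e.g. a participant who
never fixates the answer bank) yield explicitly missing values, never
infinities; the modelling layer drops and counts such participants.

## Scanpath clustering

Each trial's collapsed sequence is pooled to 10 AOIs (answer choices merged,
then re-collapsed), converted to a transition-count matrix, and
row-normalized; rows with no outgoing moves stay all-zero rather than
uniform, because a uniform row would fabricate transitions never observed.
The 90 off-diagonal probabilities feed a two-centroid k-means (within-cluster
sum of squared Euclidean distances, 25 seeded k-means++ restarts, best
objective kept). Labels are canonically oriented by answer-entry mass — the
centroid with the larger total probability of moving into the answer region
is cluster 2 — so "cluster 2" is stable across seeds whenever the data are
separable. On ≤ 8 points the fitted objective equals the exhaustive
2-partition optimum in the test suite. All trials identical is reported as a
degenerate one-cluster model with a warning, not an error. A per-choice
(17-AOI) representation was deliberately not made the default: the cluster
portraits of interest concern row/column structure within the matrix plus
answer entries, and pooling keeps the feature space small relative to the
number of trials.

Cluster contrasts use a two-sample JZS Bayes factor per metric at the trial
level (clusters are trial-level objects): BF10 is computed by quadrature
over the g-prior mixture representation of a Cauchy(0, 0.707) prior on the
standardized difference, and labelled with the conventional 3 / 10 / 100
evidence thresholds and their reciprocals.

## Penalized score prediction

Metrics and the target score are z-scored with *training-part* statistics
only (applied to both parts), after a seeded participant-level 80/20 split
(nearest-integer train size). λ is selected by leave-one-out CV: for each of
100 log-spaced penalties from the analytic λ_max = max|xᵀy|/n down to
λ_max·10⁻⁴, the LOOCV RMSE aggregates n single-left-out refits (computed as
one coordinate-descent path per fold; the equivalence with a literal
refit-per-(fold, λ) loop is asserted in tests). Ties in the minimum resolve
toward the larger penalty. Final coefficients are refit on the whole
training part at λ*. Coordinate descent is scikit-learn's cyclic
soft-thresholding solver; the path scoring uses the solver's standard
duality-gap tolerance (1e-4) and the final refit a tight one (1e-8), so the
analytic properties — exactly zero coefficients at λ ≥ λ_max, the
least-squares limit as λ → 0 — hold to 1e-6 or better. Test-set R² is
`1 − SS_res/SS_tot` about the test-set mean and may be negative; with ~12
held-out participants all four performance estimates are volatile, which the
documentation of any single run should acknowledge.

Train-only standardization avoids leakage; a whole-sample z-scoring flag
exists for comparison runs against datasets analysed that way.

## Dependent-correlation comparisons

For two correlations sharing a variable (one gaze metric against two
cognitive tests in the same sample), the z statistic Fisher-transforms the
two correlations and scales their difference by the Dunn–Clark covariance
evaluated at the individual sample correlations:

    z = (z_jk − z_jh) · sqrt((n − 3) / (2 − 2s)),
    s = ψ / ((1 − r_jk²)(1 − r_jh²)),
    ψ = r_kh(1 − r_jk² − r_jh²) − r_jk r_jh (1 − r_jk² − r_jh² − r_kh²)/2.

The sign-ignored mode takes absolute values of the two compared correlations
(the test–test correlation stays signed) before the transform, comparing
strength of association regardless of direction. This variant reproduces the
reference value z = 2.24 ≈ 2.2 from (−0.37, 0.03, 0.16, n = 69) and is
type-I calibrated to within [0.04, 0.06] at α = 0.05 under a trivariate-
normal null in 10,000 simulations. The pooled-r̄ Steiger variant was not
used. Confidence intervals are Fisher-z: `tanh(atanh(r) ± z_crit/√(n−3))`.

Correlation matrices are pairwise-complete Pearson with a minimum of 4
complete rows per pair and an error on zero-variance columns. No
multiple-testing correction is applied at this layer.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes — it
is a study-condition definition, not a fitted model of any dataset.

* **Strategies.** Two first-order Markov kernels over the 10 clustering
  AOIs: *constructive* walks the matrix in reading order with answer entries
  almost exclusively after the bottom row; *hybrid* mixes row-wise and
  column-wise moves with elevated answer entry from the end of every row. A
  separability knob linearly interpolates the hybrid kernel toward the
  constructive one (0 = identical, 1 = fully distinct, the default). Each
  participant draws a Beta(2, 2) propensity of using the hybrid kernel on a
  given trial; the per-trial kernel choice is the planted ground truth.
* **Events.** Chain length per trial is negative-binomial (mean 22,
  dispersion 20); each matrix-cell visit emits 1 + Poisson(0.8) fixations and
  each answer-region entry a run of 1 + Poisson(0.8) concrete choices (the
  correct choice drawn with a participant-specific preference, mean 0.35)
  with 1 + Poisson(0.4) fixations each; durations are lognormal per AOI side
  (medians 260/230 ms, σ = 0.3) floored at 100 ms; coordinates sit at the
  AOI centre with within-rectangle jitter; every trial starts with a
  screen-centre fixation for the first-fixation filter to remove. A 5%
  contamination fraction (sub-100 ms or off-AOI events) exercises the
  filters; 3 practice trials are generated and flagged.
* **Individual differences.** Participants additionally differ in per-side
  fixation tempo (lognormal σ = 0.4 multipliers on the duration medians),
  answer-run length (σ = 0.5), extra-fixation rate (σ = 0.6), and
  answer-entry tendency within *both* kernels (σ = 0.3 multiplier on the
  matrix→answer probabilities, renormalized). These spreads exist because
  real cohorts vary in checking style and tempo independently of strategy;
  without them every answer-side metric collapses onto a single latent
  strategy factor and no feature-selection method could tell the metrics
  apart — the planted-recovery guarantee below would be unattainable for
  structural, not statistical, reasons.
* **Scores.** Each score is a linear function of the participant's *true*
  metrics (recomputed from the emitted fixations by the metric module, with
  the cluster-share metric taken from the planted labels) plus Gaussian
  noise scaled so the signal explains a target share of variance (default
  0.6 for the primary score). The primary score loads on exactly
  matrix–answer transitions (+0.6), the dwell ratio (+0.6) and wrong-answer
  visits (−0.6) in z units; the mixed signs follow the directions reported
  for reasoning-score models in this literature (more toggling and fewer
  wrong-answer revisits predicting higher scores) and keep the signal from
  degenerating into a single answer-engagement factor.

What the generator does **not** emulate: saccade dynamics, drift and
microsaccades, item-difficulty effects, response times, and any dependence
of strategy on item position. Passing tests on synthetic data therefore
demonstrate the pipeline's internal correctness and its behaviour under the
assumed structure — not that real matrix-reasoning data satisfy that
structure.

## Verified guarantees (test suite)

With the defaults above and fixed seeds, the suite verifies: clustering
recovers planted trial strategies at ≥ 95% (measured 98.6%) under separable
kernels and falls to chance (measured 50.4%, within [0.45, 0.55]) at
separability 0; the LASSO pipeline recovers all three planted predictors
with correct signs in 48 of 50 replicated studies with median held-out R²
0.42; the Steiger test's empirical type-I error at α = 0.05 is 0.0494 over
10,000 null replicates; counting/normalization identities hold over 10,000
random inputs each; and two runs of the full pipeline on the same bundle and
seed produce byte-identical outputs. Problem sizes in the suite (60 × 18 for
study-level checks, smaller bundles for plumbing tests) were chosen as the
generator's canonical study conditions.

## Known limitations

* The metric aggregation convention (totals vs means) and the trial-time
  source are defensible choices, not reconstructions; datasets analysed
  under other conventions will differ numerically.
* Single-split test-set estimates at n ≈ 60 are volatile; the negative R²
  values that occasionally appear are informative about that volatility, not
  bugs.
* LASSO coefficient inference (CIs, p-values) is deliberately absent;
  selected-coefficient magnitudes are biased by selection.
* The Bayes-factor contrasts treat trials as exchangeable units within
  clusters; participant-level dependence is ignored at that layer.
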