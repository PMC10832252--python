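# Methods

## The projection primitive

Every model in `netpls` is assembled from one four-step operation on a
column-centered matrix `X_a` (N subjects × V variables):

1. choose a unit-length weight vector `w_a`;
2. score `t_a = X_a w_a`;
3. loading `p_a = X_a^T t_a / (t_a^T t_a)`;
4. deflate `X_{a+1} = X_a − t_a p_a^T`.

Deflation makes successive scores mutually orthogonal and each residual
matrix orthogonal to every extracted score, so sums of squares removed by
successive components add exactly.  The criteria differ only in how `w_a`
is chosen:

* **PCA** — iterate `w ← p/‖p‖` to a fixed point (power iteration on the
  Gram matrix `X_a^T X_a`).  Convergence tolerance 1e-13 on the weight
  change, at most 20 000 iterations; the iteration count and tolerance are
  implementation choices (the construction itself does not prescribe
  them).  Components whose explained sums of squares tie to within 1e-6
  relative are flagged as a degenerate subspace: within such a subspace
  the individual directions are arbitrary, only their span is defined.
  Sign convention: each component is flipped so its largest-magnitude
  loading entry is positive, which makes results deterministic across
  platforms.
* **PLS1** — `w_a = X_a^T y / ‖X_a^T y‖`, the normalized covariances of the
  deflated predictors with the outcome; the outcome itself is never
  deflated (for a single outcome this is algebraically equivalent to
  outcome-deflating variants, and it matches the four-step algorithm
  literally).  The regression vector is recovered as
  `b = W (P^T W)^{-1} q`, where `q_a = y^T t_a/(t_a^T t_a)`; in this
  deflation scheme `P^T W` is unit upper triangular, so the inverse is a
  cheap, numerically stable triangular solve.  Extraction stops early,
  with a warning, when `‖X_a^T y‖` falls below 1e-12 of its initial value:
  the remaining directions carry no predictive covariance, and forcing
  further components would only walk through machine-epsilon noise.
* **Target projection (TP)** — a single pass with `w_TP = b/‖b‖`.  The
  target score is proportional to the fitted outcome, so the one component
  carries exactly the explained outcome variance of the full PLS model
  while giving a single loading pattern to interpret.  The score is
  oriented to correlate positively with the fitted outcome, which fixes
  the signs of all downstream importance measures.
* **Covariate projection (CP)** — a single pass with an indicator weight on
  one column of the augmented matrix `[y | Z | X]`.  Every column is
  residualized on that covariate (`c ← c − z(z^T c)/(z^T z)`) and the
  covariate's own residual column is set exactly to zero.  A covariate
  whose residual variance is below 1e-12 of the mean column variance is
  rejected as degenerate rather than silently skipped.

## Component-count validation

`monte_carlo_validate` repeats, `n_rep` times: draw
`floor(split_fraction·N)` subjects without replacement as a calibration
half; center and scale both halves **using calibration statistics only**
(no information from the prediction half enters the fit); fit PLS1 with
0..`A_max` components; record the prediction cost (RMSEP by default, MAE
optionally) on the held-out half.  The 0-component reference model
predicts the calibration mean, which anchors the "one component less"
comparison at A = 1.

Selection: take the component count with the lowest median cost (smallest
count on exact ties), then walk downward while the fraction of that
model's cost distribution strictly exceeding the median of the
(A−1)-component model is at least the threshold.  The walk re-tests each
adjacent pair until one is accepted or A = 0.  Ties count as "not
exceeding".  The threshold (default 0.5) guards against overfitting; data
with a low subject-to-variable ratio warrant a lower value, and the
package exposes it as a parameter rather than automating that judgement.
A calibration draw that produces a zero-variance column is redrawn (at
most 10 times, with a warning).

Defaults (`n_rep = 1000`, 50/50 split, RMSEP) follow common practice for
cohort-sized data; the PRNG seed is recorded in the result so every
distribution is reproducible bit for bit.

## Covariate adjustment and the variance ledger

Univariate covariates are projected directly.  A multicollinear — even
rank-deficient — covariate block is first compressed: a validated PLS1
model of the outcome on the block, post-processed by TP, yields one target
score standardized to unit sample variance ("standardized" is read as
unit variance, consistent with the rest of the pipeline).  The score is
appended to the augmented matrix and projected out like any covariate, so
the block's own columns are adjusted too and the block's variance pattern
appears in the ledger alongside the other covariates.  Compression is fit
on unadjusted data; the stepwise default order is the user-supplied list,
univariate covariates first.

Every projection records, per column, the sum of squares it removed.
Because successive projection scores are mutually orthogonal, these
ledger entries plus the final residual reconstruct each column's original
sum of squares exactly, and the original (pre-adjustment) variance is the
denominator of every reported percentage — net matrices are deliberately
**not** re-standardized between steps.  Ledger entries for correlated
covariates depend on projection order (the shared variance goes to
whichever is projected first); the final net data depends only on the
span of the projected scores.

The net model is a validated PLS1 + TP fit of the net outcome on the net
explanatory variables.  When validation selects zero components the run
returns an explicit null-model marker rather than an arbitrary fit.

## Variance partition and importance

For each variable, the partition lists one fraction per covariate
projection, a net part (`‖t_TP p_i‖²` for explanatory variables, the SS of
the fitted net outcome for the outcome), and a residual closing the row to
1.  Block tables aggregate by SS-weighted mean (a plain mean once all
variables are standardized): "remaining" is the residual-plus-net share,
"explained" the net share, both as percent of original variance.

Selectivity fraction: `SF_i = ‖t_TP p_i‖²/‖x_i‖²`, signed by the loading
with the score oriented toward the fitted outcome — the sign rule is a
package convention (the measure itself only defines the magnitude).
Selectivity ratio divides by the residual `‖x_i − t_TP p_i‖²` instead;
numerically infinite ratios are capped at 1e6 and flagged.  Monte Carlo
confidence limits for SF refit PLS(+TP) with the pre-selected component
count on repeated calibration halves and take empirical type-7 quantiles
(2.5/50/97.5%) of the per-variable SF distribution.  Deriving per-variable
limits from the same resampled model ensemble is the package's documented
interpretation; a cost-error distribution alone cannot yield per-variable
limits.

## Synthetic cohorts and ground truth

The generator emulates a school-cohort lifestyle study as a linear
Gaussian structural model: a binary sex indicator (Bernoulli 0.5) and a
continuous age; 3 adiposity variables with common within-block correlation
0.8; a 23-interval physical-activity spectrum with AR(1) serial
correlation 0.9 along the intensity index and a mild negative cross-block
correlation (−0.15) to adiposity; a 26-column lipoprotein-like mediator
generated **exactly** from 4 latent factors (rank 4, optionally plus
duplicated columns); and an outcome driven by direct lifestyle effects,
the factor channel, the confounders, and Gaussian noise (SD 2.1).  Default
effect sizes were chosen so the population quantities sit at realistic
cohort magnitudes: ~28% of outcome variance explainable after confounder
adjustment, ~12% after mediator adjustment (mediated share ~0.16), and a
mediator-score/outcome correlation of ~0.41.  An option exponentiates all
non-confounder marginals so a log-transform-then-standardize pipeline
recovers the Gaussian scale.

Because every observed variable is linear in independent sources, the
population covariance is available in closed form.  Ground truth is
computed from it by independent covariance algebra — the mediator's
population target direction is the minimum-norm least-squares solution
`Σ_Z⁺ σ_Zy`, and residualization is a Schur complement — never by the
package's own projection code, so it can serve as a genuine oracle: the
pipeline run on an exact factorization of the population correlation
matrix must reproduce the truth to 1e-8, and sampled cohorts must recover
the net pattern (correlation > 0.95 at N = 800) and the mediated share
(within Monte Carlo spread across seeds).

What the generator does **not** emulate: accelerometer count
distributions, lipoprotein physiology beyond the covariance structure,
missing data, or non-linear relations.  Passing recovery tests therefore
demonstrate correctness of the algebra and the estimation chain under the
stated linear model, not robustness to real-data pathologies.

## Reproducing the published cohort analysis

`netpls.study` documents the column layout under which the published
836-subject baseline table (insulin resistance, age/sex, adiposity, PA
spectrum, 26 lipoprotein features) can be dropped into `data/` to run the
cohort-reproduction acceptance tests: the mediator model (4 components,
24.4% of outcome variance, target component 32.7% of lipoprotein
variance), the covariate correlation table, the stepwise variance table,
and the post-adjustment model with lipoproteins re-included.  The dataset
is not redistributed with the package; without it those tests report as
failures with a clear message, while everything else runs on synthetic
data alone.

## Problem sizes

The default test-suite and acceptance-script sizes — cohorts of 200–836
subjects, 150–1000 Monte Carlo repetitions, 20 recovery seeds — were
chosen so that each statistical check has comfortable margin against its
own Monte Carlo noise while a full run stays fast on a single CPU.

## Known limitations

* PLS2 (several simultaneous outcomes) is out of scope; one outcome at a
  time.
* Mediation is quantified purely as explained-variance change; no causal
  or indirect-effect inference is attempted.
* Missing values are a validation-time report and a modelling-time hard
  error; no imputation.
* The residual matrix after the total model can be exported but is not
  further analyzed (e.g. by PCA) inside the package.
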