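# netpls

**Net predictive association patterns in multicollinear data.**

`netpls` is a Python toolkit for epidemiological and metabolomics-style
regression problems in which both the explanatory variables *and* the
covariates are strongly multicollinear — up to exact linear dependence —
so that classical multiple linear regression with mutual adjustment is
unusable.  It answers questions of the form: *how much of the association
between an outcome and a block of correlated lifestyle or omics variables
remains after removing the influence of confounders and of a
high-dimensional mediator, and what does the remaining ("net") pattern
look like variable by variable?*

Everything is built from one latent-variable projection primitive.  For a
column-centered matrix `X_a` and a unit weight `w_a`:

    t_a = X_a w_a,   p_a = X_a^T t_a / (t_a^T t_a),   X_{a+1} = X_a − t_a p_a^T

Choosing `w_a` by different criteria yields:

* **PCA** (`w` a fixed point of the loading iteration),
* **PLS1 regression** (`w_a = X_a^T y / ‖X_a^T y‖`), with the number of
  predictive components selected by repeated Monte Carlo resampling:
  random calibration/prediction splits, a cost distribution (RMSEP or
  MAE) per component count, and selection of the lowest-median model
  guarded by an exceedance-fraction rule against overfitting,
* **target projection** (`w_TP = b/‖b‖`), collapsing a validated
  multi-component PLS model into a single predictive component `t_TP,
  p_TP` that preserves the model's explained outcome variance,
* **covariate projection** (an indicator weight on one column of the
  augmented matrix `[y | Z | X]`), residualizing the outcome and every
  other column on a covariate in one pass.

A rank-deficient multivariate covariate (e.g. a 26-feature lipoprotein
profile acting as a mediator) is handled by compressing it to its
predictive **target score** — PLS of the outcome on the block, then target
projection — and projecting on that score.  The result is a single joint
model that partitions each variable's variance into orthogonal parts
(one per covariate, a net predictive part, a residual),

    X = X̂_cov,1 + … + X̂_cov,n + t_net,TP p_net,TP^T + E,

with per-variable importance measured by the signed selectivity fraction
`SF_i = ‖t_TP p_i‖²/‖x_i‖² ∈ [−1, 1]` (or the selectivity ratio, which
divides by residual variance instead), with Monte Carlo confidence
limits.

## Worked example

The built-in generator draws a realistic cohort — an outcome, two
confounders (`age`, `sex`), a rank-4 mediator block of 26 correlated
features, and 26 explanatory lifestyle variables — with a known
population ground truth:

```python
import numpy as np
from netpls import (FixtureSpec, generate, preprocess, RunConfig,
                    stepwise_analysis)

spec = FixtureSpec(n_subjects=836, seed=7)
table, truth = generate(spec)
proc = preprocess(table)                      # center + unit variance
names = spec.column_names()

cfg = RunConfig(n_rep=1000, A_max=7, seed=1)
res = stepwise_analysis(proc, "outcome", ["age", "sex"],
                        {"mediator": names["mediator"]},
                        names["adiposity"] + names["pa"], config=cfg,
                        with_importance=False)

comp = res.compressions["mediator"]
print("mediator: A =", comp.selected_A,
      "| explains %.1f%% of outcome, %.1f%% of block"
      % (100 * comp.explained_y_fraction, 100 * comp.explained_block_fraction))
print(res.block_table().round(1).to_string())
print("net pattern corr with truth: %.3f"
      % np.corrcoef(res.final.net.tp.loading, truth.net_pattern)[0, 1])
```

prints

```
mediator: A = 1 | explains 19.1% of outcome, 60.4% of block
                      remaining_outcome  explained_outcome  remaining_mediator  explained_mediator  remaining_explanatory  explained_explanatory
stage
unadjusted                        100.0               28.3               100.0                 0.0                  100.0                   29.5
age                                99.6               28.2                99.9                 0.0                   99.3                   28.9
age + sex                          99.3               27.9                99.7                 0.0                   98.2                   28.4
age + sex + mediator               80.1               10.6                39.4                 0.0                   83.7                   13.5
net pattern corr with truth: 0.982
```

Reading the table: the validated model initially explains 28.3% of the
outcome's variance; the confounders barely matter; projecting out the
mediator's target score removes ~20% of the outcome's variance and drops
the net model to 10.6% — the mediated share of the association — while
the recovered net loading pattern matches the generator's analytic
population pattern (r = 0.982).  `remaining_*` columns are percent of
each block's original variance left after the covariate projections;
`explained_*` is the share captured by the net target component.

The same chain is scriptable from the shell:

```bash
netpls simulate --seed 7 --out cohort.csv --truth truth.json
netpls run --config analysis.yaml        # validate → compress → adjust → model
netpls importance cohort.csv --outcome outcome --components 3 --out sf.csv
```

(`netpls --help` lists the stage-by-stage subcommands: validate,
preprocess, correlate, pca, validate-pls, compress-covariate, adjust,
net-model, partition, importance, simulate, run.)

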