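# Methods

## The problem

In symbolic data analysis a quantitative observation is often an interval
`[a, b]` rather than a single number — a patient's pulse over a day, the
min/max purchase on a credit card. `intervalreg` fits regression models in
which every predictor and the response are interval-valued: given
intervals `x_ij = [a_ij, b_ij]` and `y_i = [y_Li, y_Ui]`, predict the
response interval for new cases.

Both methods implemented here reduce the problem to ordinary point
regression through two real-valued views of an interval: its **center**
`x^c = (a + b) / 2` and its **half-range** `x^r = (b - a) / 2`.

## Center method (CM)

Fit one point regressor `f` on the midpoint data `(X^c, y^c)` and predict
the bounds by evaluating the fitted function at the endpoint vectors:

    yhat_L = f(x^L),   yhat_U = f(x^U),

with `x^L = (a_1, ..., a_p)` and `x^U = (b_1, ..., b_p)`. In the linear
case `f(x) = x' beta_hat` with `beta_hat = ((X^c)' X^c)^{-1} (X^c)' y^c`
(computed here by a QR least-squares factorization, not the literal
inverse).

## Center-and-range method (CRM)

Fit two point regressors: `f_c` on `(X^c, y^c)` and `f_r` on the
half-range data `(X^r, y^r)`. The prediction is

    yhat_c = f_c(x^c),  yhat_r = f_r(x^r),
    yhat_L = yhat_c - yhat_r,   yhat_U = yhat_c + yhat_r.

Hyperparameter selection (penalty path, K, ...) runs independently in the
two regressions, since they are separate models on separate data.

Neither rule can guarantee `yhat_L <= yhat_U`: CM inverts the bounds
wherever `f` is decreasing (a linear model with any negative coefficient),
CRM wherever the predicted half-range is negative. Predictions are
returned exactly as computed with a per-row `reversed_flag`; they are
never silently reordered. Constrained variants that enforce the ordering
are deliberately out of scope.

The prediction rules are independent of the base-learner family, so the
two meta-estimators (`CenterMethodRegressor`, `CenterRangeMethodRegressor`)
are written once against a scikit-learn-style fit/predict contract.

## Base regressor families and defaults

All defaults are the benchmark settings used in the package's evaluation
harness; they can be overridden per fit through `RegressorSpec`.

| family | default configuration |
|---|---|
| `lm`    | ordinary least squares, internal intercept; rank-deficient designs raise, naming the collinear columns; zero-variance columns get coefficient 0 (this is what makes degenerate-interval data fit cleanly) |
| `ridge`, `lasso` | penalty chosen by 10-fold CV on a 100-point log grid from `lambda_max` (the smallest penalty zeroing all lasso coefficients) down to `lambda_max * 1e-4`; predictors z-scored for penalization, coefficients reported on the original scale; leave-one-out fallback with a warning when n cannot support 10 folds of >= 3 rows |
| `tree`  | CART, greedy binary splits minimizing RSS; a node is splittable at >= 20 observations, children must hold >= ceil(20/3) = 7, max depth 10 |
| `rf`    | 500 bootstrap trees, `floor(p/3)` (min 1) candidate variables per split |
| `boost` | squared-error gradient boosting: 500 depth-1 trees (stumps), shrinkage 0.1 |
| `knn`   | Euclidean distance on z-scored predictors; K selected in 1..20 by leave-one-out RMSE; triangular kernel: neighbor distances normalized by the (K+1)-th neighbor distance, weight `1 - d/d_(K+1)`, exact duplicates get maximal weight 1 |
| `svm`   | epsilon-insensitive SVR, RBF kernel, C = 1, epsilon = 0.1, gamma = 1/p on standardized predictors |
| `nnet`  | one hidden layer of 10 sigmoid units, linear output; inputs and response min-max scaled to [0, 1]; trained full-batch by iRprop- on half the sum of squared errors until the largest absolute gradient entry is below 0.05, capped at 1e5 steps (best-so-far parameters kept, with a warning, if the cap is hit); standard-normal weight initialization under the given seed |

Standard learners (ridge/lasso paths, CART, forests, boosting, SVR) are
provided by scikit-learn behind this surface. OLS, the triangular-kernel
KNN, and the iRprop- network are implemented natively because their exact
semantics (rank diagnostics with constant-column tolerance, the
(K+1)-th-distance kernel normalization, the gradient-threshold stopping
rule) are not available in an installed library.

Design notes on the ensembles: boosting is squared-error *gradient*
boosting with stumps — that is the configuration the shrinkage and
interaction-depth parameters describe; AdaBoost-style observation
reweighting is not meaningful for squared-error regression. Tie-breaks in
tree splitting follow scikit-learn's deterministic left-to-right scan;
split thresholds are midpoints between consecutive sorted values.

## Error metrics

Accuracy is scored separately on the two bounds:
`RMSE_L = sqrt(mean((y_L - yhat_L)^2))`, likewise `RMSE_U`, and the
squared Pearson correlations `r2_L`, `r2_U` between true and predicted
bounds. A squared correlation is undefined whenever either standard
deviation is zero (e.g., a single-leaf tree predicting one constant); it
is carried as NaN and rendered exactly as `NA`. Population (divide-by-n)
normalization is used throughout; the choice cancels in the correlation
ratio.

## Synthetic designs

**Linear (D1-D4), 375 rows, 3 predictors.** Midpoints
`X_j^c ~ U[20, 40]`; `Y^c = beta_0 + sum_j beta_j X_j^c + eps` with
`beta ~ U[-10, 10]`. Half-ranges are linearly tied to midpoints:
`Y^r = Y^c b* + eps*`, `X_j^r = X_j^c b*_j + eps*`, `b* ~ U[0.5, 1.5]`
drawn independently per relation (a shared-draw variant is a config
switch). D1-D4 cross midpoint noise `U[-20,20]` vs `U[-5,5]` with
dependence noise `U[1,5]` vs `U[10,20]`. Because `Y^c` can be negative, a
simulated half-range can come out negative; such values are clipped to 0
and the count is stored in the truth record. The conventional split is
the first 250 rows for training, 125 for testing (the harness's
`train_fraction=250/375` floor rule reproduces it in expectation of the
seeded permutation).

Note that absolute metric levels on these designs are dominated by the
single `beta` draw, so they vary by orders of magnitude across seeds;
only qualitative comparisons (CRM vs CM ordering, slope recovery) are
stable.

**Nonlinear, 3000 rows, 3 predictors.** Midpoints `X_j^c ~ U[-6, 6]` with
a logistic response

    Y^c = th0c / (th1c + exp(th2c X_1^c + ... + th4c X_3^c)) + eps^c,

`th0c ~ U[1.9, 2.1]`, `th1c ~ U[2.9, 3.1]`, remaining `th ~ U[0.9, 1.1]`,
`eps^c ~ N(0, sd 0.05)`. Half-ranges `X_j^r ~ U[1, 4]` with an exponential
response `Y^r = th0r + exp(-(th1r X_1^r + ...)) + eps^r`,
`th0r ~ U[0, 0.5]`, remaining `th ~ U[0.9, 1.1]`, `eps^r ~ N(0, sd 0.01)`.
Coefficients are drawn once per dataset. The noise parameters are
standard deviations; with them, the best attainable bound RMSE is about
`sqrt(0.05^2 + 0.01^2) ~ 0.051`, which is exactly where the strongest
CRM methods land.

What the generators do *not* emulate: measurement error in the interval
bounds themselves, dependence between predictors, heteroscedastic or
heavy-tailed noise, missing data, and non-rectangular symbolic structure.
Passing benchmarks on these designs therefore demonstrates correctness of
the method algebra and the expected method ordering under clean
conditions, not performance on any particular real dataset.

## Evaluation harness

`holdout_eval` uses one seeded permutation shared by every method
(`floor(0.7 n)` training rows by default); `kfold_eval` deals a seeded
permutation into k near-equal folds, computes metrics per fold, and
reports fold means and fold standard deviations (n-1 denominator) —
per-fold-then-average, never pooled. All randomness (split, fold deal,
each learner's internal seed) derives from one master seed via
`numpy.random.SeedSequence` spawning, so a whole benchmark reproduces
from a single integer. A method that fails to fit is reported as an `NA`
row with its error message; the other methods are unaffected.

## Problem sizes used by the test suite

The packaged checks run the nonlinear benchmark at its native size
(n = 3000, 10-fold CV for the fold-mean metric levels; three master seeds
of a single 70/30 holdout for the CRM-vs-CM ordering and the
network-vs-linear ratio, since that ordering is structural rather than
fold-dependent). Unit and property tests use small synthetic instances
(n = 10-120) with brute-force or closed-form oracles.

## Numerical choices and edge cases

- Degenerate intervals (`a == b`) are legal everywhere and reduce both
  methods to classical point regression; the CRM range model then sees
  all-zero data and fits an exact zero function (for lm/tree/knn).
- OLS treats a column as constant when its spread is below `1e-10`
  relative to its magnitude; such columns get coefficient 0 rather than
  tripping the rank check.
- KNN ties and duplicates: zero-distance neighbors receive weight 1; a
  zero bandwidth (all duplicates) degrades to an unweighted mean; K
  selection breaks ties toward the smaller K.
- The rprop stopping threshold applies to the gradient of half-SSE in the
  scaled space; the reported model is always the lowest-error iterate
  observed.
- Interval CSV I/O parses floats in round-trip precision mode, so
  write-then-read is bit-exact.

## Known limitations

- No constrained fit enforcing `yhat_L <= yhat_U` (reversed predictions
  are flagged instead).
- Predictors must be numeric intervals; no categorical, histogram, or
  multi-valued symbolic types.
- No significance testing between methods in the harness.
- The RBF-SVR and penalized-linear families delegate to libsvm/sklearn
  solvers; their tolerance knobs are not re-exported.
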