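# intervalreg

Regression for **symbolic interval-valued data**: every predictor and the
response take values that are closed intervals `[a, b]` rather than
single numbers (a patient's pulse range over a day, a day's min/max
temperature, a customer's smallest/largest purchase). The package is
aimed at statisticians and data scientists working with aggregated or
uncertainty-carrying data who want to move beyond linear interval models.

## The methods

Write each interval through its center `x^c = (a+b)/2` and half-range
`x^r = (b-a)/2`. Two classical reductions to point regression are
provided as scikit-learn-style meta-estimators over any base regressor
`f`:

- **Center method (CM)** — fit `f` on `(X^c, y^c)`; predict
  `ŷ_L = f(x^L)`, `ŷ_U = f(x^U)` at the endpoint vectors.
- **Center-and-range method (CRM)** — fit `f_c` on `(X^c, y^c)` and
  `f_r` on `(X^r, y^r)`; predict `ŷ_L = ŷ_c − ŷ_r`, `ŷ_U = ŷ_c + ŷ_r`.

Nine base families are supported behind one contract: `lm`, `ridge`,
`lasso`, `tree` (CART), `rf` (random forest), `boost` (gradient-boosted
stumps), `knn` (triangular-kernel, leave-one-out-selected K), `svm`
(RBF support-vector regression), and `nnet` (a single-hidden-layer
sigmoid network trained by resilient backpropagation). Neither method
can guarantee `ŷ_L ≤ ŷ_U`; reversed predictions are returned as computed
and flagged, never reordered. Accuracy is scored per bound with
`RMSE_L`, `RMSE_U` and the squared correlations `r²_L`, `r²_U`.

Monte Carlo generators for a linear interval design (configurations
D1–D4) and a nonlinear logistic/exponential design, plus a
holdout/K-fold benchmark harness over the full method roster, round out
the package. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from intervalreg import simulate, fit_cm, fit_crm, metrics_row, metrics_table
from intervalreg.metrics import render_markdown

data = simulate("nonlinear", seed=42, n=600)      # interval X (600x3), interval y
train, test = np.arange(400), np.arange(400, 600)
Xtr, ytr = data.X.take(train), data.y.take(train)
Xte, yte = data.X.take(test), data.y.take(test)

rows = []
for label, model in [
    ("LM CM",   fit_cm(Xtr, ytr, "lm")),
    ("LM CRM",  fit_crm(Xtr, ytr, "lm")),
    ("KNN CRM", fit_crm(Xtr, ytr, "knn")),
]:
    rows.append(metrics_row(yte, model.predict_interval(Xte), label))
print(render_markdown(metrics_table(rows)))
```

Output:

```
| Method | RMSE_L | RMSE_U | r2_L | r2_U |
|---|---|---|---|---|
| LM CM | 0.5540 | 0.5734 | 0.7378 | 0.7309 |
| LM CRM | 0.1395 | 0.1393 | 0.7791 | 0.7774 |
| KNN CRM | 0.0730 | 0.0741 | 0.9399 | 0.9375 |
```

The response midpoints here follow a logistic curve, so the linear center
method misses badly on the bounds (RMSE ≈ 0.55). Modelling centers and
half-ranges separately (LM CRM) cuts the bound error to 0.14 — the
residual bias of a straight line through a sigmoid — and a nonlinear base
learner under CRM approaches the design's noise floor
(`sqrt(0.05² + 0.01²) ≈ 0.051` at full sample size; 0.073 here at
n = 600) while raising the bound correlations to ≈ 0.94.

Interval tables are read and written as paired-column CSV
(`V.lower`, `V.upper` per variable): `read_interval_csv(path,
response="Y")`. The same workflow is scriptable from the shell:

```sh
intervalreg simulate --design nonlinear --seed 42 -o out/
intervalreg fit --data out/data.csv --response Y --mode crm --family knn -o out/model.pkl
intervalreg predict --model out/model.pkl --data out/data.csv -o out/pred.csv
intervalreg benchmark --design nonlinear --cv 10 --seed 7 -o out/bench/
```

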