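"""Point-valued base regressors behind one fit/predict contract.

The interval meta-estimators in :mod:`intervalreg.methods` are written once
against plain scikit-learn regressor semantics (``fit(X, y)`` /
``predict(X)`` on real matrices).  This module provides

* a declarative :class:`RegressorSpec` (family + hyperparameters + seed)
  whose defaults are the benchmark settings used throughout the package;
* native estimators where no installed library offers the required
  semantics: ordinary least squares with rank diagnostics
  (:class:`LeastSquaresRegressor`), triangular-kernel K-nearest-neighbor
  regression with leave-one-out selection of K
  (:class:`TriangularKNNRegressor`), a single-hidden-layer sigmoid network
  trained by resilient backpropagation with a max-gradient stopping rule
  (:class:`RPropNetRegressor`), and cross-validated ridge/lasso over a
  data-driven log-spaced penalty grid (:class:`PenalizedLinearCV`);
* scikit-learn estimators configured to the benchmark defaults for the
  remaining families (CART tree, random forest, gradient-boosted stumps,
  RBF support-vector regression).

Default hyperparameters by family
---------------------------------
==========  ==============================================================
lm          ordinary least squares (intercept added internally)
ridge       penalty chosen by 10-fold CV on a 100-point log grid
lasso       same CV scheme; coordinate descent to tolerance 1e-7
tree        CART, node splittable at >= 20 observations, children >= 7,
            max depth 10
rf          500 bootstrap trees, floor(p/3) (min 1) candidate variables
            per split
boost       500 depth-1 trees (stumps), shrinkage 0.1, squared-error loss
knn         K selected in 1..20 by leave-one-out RMSE, triangular kernel,
            Euclidean distance on z-scored predictors
svm         epsilon-insensitive SVR, RBF kernel, C=1, epsilon=0.1,
            gamma=1/p on standardized predictors
nnet        1 hidden layer of 10 sigmoid units, linear output, min-max
            scaled inputs/response, iRprop- until max|gradient| < 0.05 or
            1e5 steps
==========  ==============================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, LassoCV, Ridge, RidgeCV
from sklearn.model_selection import KFold
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "FAMILIES",
    "DEFAULT_HYPERPARAMETERS",
    "RegressorSpec",
    "LeastSquaresRegressor",
    "PenalizedLinearCV",
    "TriangularKNNRegressor",
    "RPropNetRegressor",
    "make_regressor",
    "fit_regressor",
    "fit_lm",
    "fit_ridge",
    "fit_lasso",
    "fit_tree",
    "fit_rf",
    "fit_boost",
    "fit_knn",
    "fit_svm",
    "fit_nnet",
]

FAMILIES = ("lm", "ridge", "lasso", "tree", "rf", "boost", "knn", "svm", "nnet")

DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "lm": {},
    "ridge": {"cv_folds": 10, "n_lambdas": 100, "lambda_min_ratio": 1e-4, "lambdas": None},
    "lasso": {"cv_folds": 10, "n_lambdas": 100, "lambda_min_ratio": 1e-4, "lambdas": None},
    "tree": {"min_split": 20, "max_depth": 10},
    "rf": {"n_trees": 500, "max_features": 1.0 / 3.0, "bootstrap": True},
    "boost": {"n_trees": 500, "learning_rate": 0.1, "interaction_depth": 1},
    "knn": {"max_k": 20, "k": None},
    "svm": {"C": 1.0, "epsilon": 0.1},
    "nnet": {"hidden": 10, "threshold": 0.05, "max_steps": 100_000},
}


@dataclass
class RegressorSpec:
    """Declarative choice of a base-learner family with hyperparameters.

    ``hyperparameters`` overrides the family defaults above; ``seed``
    controls any internal randomness (bootstrap draws, weight init).
    """

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown regressor family {self.family!r}; valid: {', '.join(FAMILIES)}"
            )
        unknown = set(self.hyperparameters) - set(DEFAULT_HYPERPARAMETERS[self.family])
        if unknown:
            raise ValueError(
                f"unknown hyperparameters for family {self.family!r}: {sorted(unknown)}"
            )

    def resolved(self) -> dict[str, Any]:
        merged = dict(DEFAULT_HYPERPARAMETERS[self.family])
        merged.update(self.hyperparameters)
        return merged

    def build(self, seed: int | None = None):
        """Instantiate an unfitted estimator for this spec.

        ``seed`` is a fallback used only when the spec itself carries none.
        """
        return make_regressor(self, seed=seed)

    def to_dict(self) -> dict[str, Any]:
        return {
            "family": self.family,
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RegressorSpec":
        return cls(
            family=d["family"],
            hyperparameters=dict(d.get("hyperparameters", {})),
            seed=d.get("seed"),
        )


# -------------------------------------------------------------------------
# Native estimators
# -------------------------------------------------------------------------


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"expected 2-D design matrix, got shape {X.shape}")
    return X


class LeastSquaresRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares with an internal intercept column.

    Solved by a QR-based least-squares factorization rather than the
    normal equations.  A rank-deficient design raises, naming the columns
    that pivot out.
    """

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        # constant columns carry nothing beyond the intercept: coefficient 0
        # (lets degenerate inputs such as all-zero half-ranges fit cleanly)
        scale = np.maximum(1.0, np.max(np.abs(X), axis=0, initial=0.0))
        varying = np.ptp(X, axis=0) > 1e-10 * scale
        A = np.column_stack([np.ones(n), X[:, varying]])
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < A.shape[1]:
            # identify collinear columns via pivoted QR
            _, _, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
            col_of = np.concatenate([[-1], np.where(varying)[0]])
            dropped = sorted(int(col_of[j]) for j in piv[rank:])
            labels = ["intercept" if j == -1 else f"column {j}" for j in dropped]
            raise np.linalg.LinAlgError(
                f"rank-deficient design (rank {rank} < {A.shape[1]}); "
                f"collinear with the rest: {', '.join(labels)}"
            )
        self.intercept_ = float(coef[0])
        self.coef_ = np.zeros(p)
        self.coef_[varying] = coef[1:]
        self.n_features_in_ = p
        return self

    def predict(self, X):
        X = _as_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was trained with {self.n_features_in_}"
            )
        return self.intercept_ + X @ self.coef_


class PenalizedLinearCV(RegressorMixin, BaseEstimator):
    """Ridge or lasso with the penalty chosen by K-fold cross-validation.

    Predictors are z-scored for penalization; reported ``coef_`` /
    ``intercept_`` are on the original scale.  The grid is 100 points,
    log-spaced from lambda_max (the smallest penalty zeroing every lasso
    coefficient) down to ``lambda_max * lambda_min_ratio``.  When ``n``
    cannot support ``cv_folds`` folds of at least 3 rows, selection falls
    back to leave-one-out with a warning.

    Passing an explicit ``lambdas`` array bypasses the data-driven grid;
    a single value skips cross-validation entirely.
    """

    def __init__(
        self,
        penalty: str = "ridge",
        cv_folds: int = 10,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-4,
        lambdas=None,
    ):
        self.penalty = penalty
        self.cv_folds = cv_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.lambdas = lambdas

    def _grid(self, Xs: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.lambdas is not None:
            return np.sort(np.atleast_1d(np.asarray(self.lambdas, dtype=float)))[::-1]
        n = Xs.shape[0]
        lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
        if lam_max <= 0:
            lam_max = 1.0
        return np.logspace(
            np.log10(lam_max), np.log10(lam_max * self.lambda_min_ratio), self.n_lambdas
        )

    def fit(self, X, y):
        if self.penalty not in ("ridge", "lasso"):
            raise ValueError(f"penalty must be 'ridge' or 'lasso', got {self.penalty!r}")
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - mu) / sd
        grid = self._grid(Xs, y)

        if len(grid) == 1:
            lam = float(grid[0])
            est = (
                Ridge(alpha=lam) if self.penalty == "ridge"
                else Lasso(alpha=lam, tol=1e-7, max_iter=100_000)
            )
            est.fit(Xs, y)
        else:
            cv: int | KFold
            if n >= 3 * self.cv_folds:
                cv = KFold(n_splits=self.cv_folds)
            else:
                warnings.warn(
                    f"n={n} too small for {self.cv_folds}-fold CV; "
                    "falling back to leave-one-out",
                    stacklevel=2,
                )
                cv = KFold(n_splits=n)
            if self.penalty == "ridge":
                est = RidgeCV(alphas=grid, cv=cv)
            else:
                est = LassoCV(alphas=grid, cv=cv, tol=1e-7, max_iter=100_000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # benign duality-gap chatter
                est.fit(Xs, y)

        coef_std = np.asarray(est.coef_, dtype=float)
        self.lambda_ = float(getattr(est, "alpha_", grid[0]))
        self.coef_ = coef_std / sd
        self.intercept_ = float(est.intercept_ - np.sum(coef_std * mu / sd))
        self.n_features_in_ = p
        return self

    def predict(self, X):
        X = _as_matrix(X)
        return self.intercept_ + X @ self.coef_


class TriangularKNNRegressor(RegressorMixin, BaseEstimator):
    """Kernel-weighted K-nearest-neighbor regression.

    Distances are Euclidean on z-scored predictors.  For a query point the
    K neighbor distances are normalized by the (K+1)-th neighbor distance
    and weighted by the triangular kernel ``w = 1 - d/d_(K+1)``; the
    prediction is the weighted mean of the neighbor responses.  Exact
    duplicates (zero bandwidth) receive maximal weight 1.  K is selected
    in ``1..max_k`` by leave-one-out RMSE on the training set.
    """

    def __init__(self, max_k: int = 20, k: int | None = None):
        self.max_k = max_k
        self.k = k  # force a fixed K, skipping leave-one-out selection

    @staticmethod
    def _weighted_mean(dist: np.ndarray, bandwidth: np.ndarray, resp: np.ndarray) -> np.ndarray:
        """Triangular-kernel mean; dist (m,k), bandwidth (m,), resp (m,k)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            w = 1.0 - dist / bandwidth[:, None]
        w[~np.isfinite(w)] = 1.0  # zero bandwidth: all-duplicate neighborhood
        w[(bandwidth[:, None] == 0) | (dist == 0)] = 1.0
        w = np.clip(w, 0.0, None)
        total = w.sum(axis=1)
        out = np.where(total > 0, (w * resp).sum(axis=1) / np.where(total > 0, total, 1.0),
                       resp.mean(axis=1))
        return out

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        if n < 2:
            raise ValueError("TriangularKNNRegressor requires n >= 2")
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - self._mu) / self._sd
        self._nn = NearestNeighbors().fit(Xs)
        self._y = y
        self.n_features_in_ = X.shape[1]

        if self.k is not None:
            self.k_ = int(self.k)
            return self

        # leave-one-out: query max_k+2 neighbors, drop each row's self entry
        k_cap = min(self.max_k, n - 2) if n > 2 else 1
        m = min(n, k_cap + 2)
        dist, idx = self._nn.kneighbors(Xs, n_neighbors=m)
        rows = np.arange(n)
        self_pos = np.argmax(idx == rows[:, None], axis=1)  # first self occurrence
        keep = np.ones_like(idx, dtype=bool)
        keep[rows, self_pos] = False
        dist = dist[keep].reshape(n, m - 1)
        idx = idx[keep].reshape(n, m - 1)
        resp = self._y[idx]

        best_k, best_rmse = 1, np.inf
        for k in range(1, min(k_cap, m - 2) + 1):
            pred = self._weighted_mean(dist[:, :k], dist[:, k], resp[:, :k])
            rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
            if rmse < best_rmse - 1e-12:
                best_k, best_rmse = k, rmse
        self.k_ = best_k
        return self

    def predict(self, X):
        X = _as_matrix(X)
        Xs = (X - self._mu) / self._sd
        k = min(self.k_, len(self._y) - 1)
        dist, idx = self._nn.kneighbors(Xs, n_neighbors=k + 1)
        return self._weighted_mean(dist[:, :k], dist[:, k], self._y[idx[:, :k]])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class RPropNetRegressor(RegressorMixin, BaseEstimator):
    """Single-hidden-layer sigmoid network trained by resilient backprop.

    Inputs and response are min-max scaled to [0, 1] internally; the output
    unit is linear.  Training minimizes half the sum of squared errors by
    iRprop- (sign-based updates with per-weight step sizes) and stops when
    the largest absolute gradient entry drops below ``threshold`` or after
    ``max_steps`` steps, in which case the best parameters seen are kept
    and a warning is emitted.  Weight initialization is standard normal,
    controlled by ``random_state``.
    """

    def __init__(
        self,
        hidden: int = 10,
        threshold: float = 0.05,
        max_steps: int = 100_000,
        random_state: int | None = None,
    ):
        self.hidden = hidden
        self.threshold = threshold
        self.max_steps = max_steps
        self.random_state = random_state

    # iRprop- step-size schedule
    _ETA_UP, _ETA_DOWN = 1.2, 0.5
    _STEP_MIN, _STEP_MAX = 1e-6, 50.0

    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self._x_min) / self._x_den

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n < 2:
            raise ValueError("RPropNetRegressor requires n >= 2")
        self._x_min = X.min(axis=0)
        den = X.max(axis=0) - self._x_min
        self._x_den = np.where(den > 0, den, 1.0)
        self._y_min = y.min()
        y_den = y.max() - self._y_min
        self._y_den = y_den if y_den > 0 else 1.0
        Xs = self._scale_x(X)
        ys = (y - self._y_min) / self._y_den

        rng = np.random.default_rng(self.random_state)
        h = self.hidden
        params = [
            rng.standard_normal((p, h)),  # W1
            rng.standard_normal(h),       # b1
            rng.standard_normal(h),       # w2
            rng.standard_normal(),        # b2 (kept as 0-d array below)
        ]
        params[3] = np.atleast_1d(params[3])
        steps = [np.full_like(q, 0.1) for q in params]
        prev_g = [np.zeros_like(q) for q in params]
        best_err, best_params = np.inf, [q.copy() for q in params]
        self.converged_ = False

        for it in range(int(self.max_steps)):
            W1, b1, w2, b2 = params
            A = _sigmoid(Xs @ W1 + b1)
            resid = A @ w2 + b2[0] - ys
            err = 0.5 * float(resid @ resid)
            if err < best_err:
                best_err = err
                best_params = [q.copy() for q in params]

            dZ = np.outer(resid, w2) * A * (1.0 - A)
            grads = [
                Xs.T @ dZ,
                dZ.sum(axis=0),
                A.T @ resid,
                np.atleast_1d(resid.sum()),
            ]
            if max(np.max(np.abs(g)) for g in grads) < self.threshold:
                self.converged_ = True
                self.n_iter_ = it + 1
                break
            for q, g, st, pg in zip(params, grads, steps, prev_g):
                sign = g * pg
                st *= np.where(sign > 0, self._ETA_UP, np.where(sign < 0, self._ETA_DOWN, 1.0))
                np.clip(st, self._STEP_MIN, self._STEP_MAX, out=st)
                g_eff = np.where(sign < 0, 0.0, g)  # iRprop-: no step after sign flip
                q -= np.sign(g_eff) * st
                pg[...] = g_eff
        else:
            self.n_iter_ = int(self.max_steps)
            warnings.warn(
                f"rprop did not reach gradient threshold {self.threshold} in "
                f"{self.max_steps} steps; keeping best parameters (sse/2={best_err:.4g})",
                stacklevel=2,
            )
            params = best_params

        if self.converged_:
            # the stopping iterate is at least as good as any earlier one in
            # gradient terms; keep the lowest-error iterate regardless
            W1, b1, w2, b2 = params
            A = _sigmoid(Xs @ W1 + b1)
            resid = A @ w2 + b2[0] - ys
            if 0.5 * float(resid @ resid) > best_err:
                params = best_params
        self.W1_, self.b1_, self.w2_, self.b2_ = (q.copy() for q in params)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        X = _as_matrix(X)
        Xs = self._scale_x(X)
        A = _sigmoid(Xs @ self.W1_ + self.b1_)
        out = A @ self.w2_ + self.b2_[0]
        return out * self._y_den + self._y_min


# -------------------------------------------------------------------------
# Factory
# -------------------------------------------------------------------------


def _coerce_spec(spec) -> RegressorSpec:
    if isinstance(spec, RegressorSpec):
        return spec
    if isinstance(spec, str):
        return RegressorSpec(spec)
    if isinstance(spec, Mapping):
        return RegressorSpec.from_dict(spec)
    raise TypeError(f"cannot interpret {spec!r} as a RegressorSpec")


def make_regressor(spec, seed: int | None = None):
    """Build an unfitted point regressor from a spec, family name, or dict.

    An already-instantiated estimator (anything with fit/predict that is
    not a spec) is cloned and returned as-is.
    """
    if hasattr(spec, "fit") and hasattr(spec, "predict"):
        return clone(spec)
    spec = _coerce_spec(spec)
    hp = spec.resolved()
    rs = spec.seed if spec.seed is not None else seed

    if spec.family == "lm":
        return LeastSquaresRegressor()
    if spec.family in ("ridge", "lasso"):
        return PenalizedLinearCV(
            penalty=spec.family,
            cv_folds=hp["cv_folds"],
            n_lambdas=hp["n_lambdas"],
            lambda_min_ratio=hp["lambda_min_ratio"],
            lambdas=hp.get("lambdas"),
        )
    if spec.family == "tree":
        min_split = hp["min_split"]
        return DecisionTreeRegressor(
            min_samples_split=min_split,
            min_samples_leaf=max(1, int(np.ceil(min_split / 3))),
            max_depth=hp["max_depth"],
            random_state=rs,
        )
    if spec.family == "rf":
        return RandomForestRegressor(
            n_estimators=hp["n_trees"],
            max_features=hp["max_features"],
            bootstrap=hp["bootstrap"],
            random_state=rs,
            n_jobs=1,
        )
    if spec.family == "boost":
        return GradientBoostingRegressor(
            n_estimators=hp["n_trees"],
            learning_rate=hp["learning_rate"],
            max_depth=hp["interaction_depth"],
            loss="squared_error",
            random_state=rs,
        )
    if spec.family == "knn":
        return TriangularKNNRegressor(max_k=hp["max_k"], k=hp.get("k"))
    if spec.family == "svm":
        # gamma='auto' = 1/p, the intended width on z-scored predictors
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svr", SVR(kernel="rbf", C=hp["C"], epsilon=hp["epsilon"], gamma="auto")),
            ]
        )
    if spec.family == "nnet":
        return RPropNetRegressor(
            hidden=hp["hidden"],
            threshold=hp["threshold"],
            max_steps=hp["max_steps"],
            random_state=rs,
        )
    raise ValueError(f"unknown family {spec.family!r}")  # pragma: no cover


def fit_regressor(X, y, spec, seed: int | None = None):
    """Build and fit a point regressor; returns the fitted estimator."""
    return make_regressor(spec, seed=seed).fit(X, y)


def fit_lm(X, y):
    return LeastSquaresRegressor().fit(X, y)


def fit_ridge(X, y, spec=None, seed=None):
    spec = spec or RegressorSpec("ridge")
    return fit_regressor(X, y, spec, seed)


def fit_lasso(X, y, spec=None, seed=None):
    spec = spec or RegressorSpec("lasso")
    return fit_regressor(X, y, spec, seed)


def fit_tree(X, y, spec=None, seed=None):
    spec = spec or RegressorSpec("tree")
    return fit_regressor(X, y, spec, seed)


def fit_rf(X, y, spec=None, seed=None):
    spec = spec or RegressorSpec("rf")
    return fit_regressor(X, y, spec, seed)


def fit_boost(X, y, spec=None, seed=None):
    spec = spec or RegressorSpec("boost")
    return fit_regressor(X, y, spec, seed)


def fit_knn(X, y, spec=None, seed=None):
    spec = spec or RegressorSpec("knn")
    return fit_regressor(X, y, spec, seed)


def fit_svm(X, y, spec=None, seed=None):
    spec = spec or RegressorSpec("svm")
    return fit_regressor(X, y, spec, seed)


def fit_nnet(X, y, spec=None, seed=None):
    spec = spec or RegressorSpec("nnet")
    return fit_regressor(X, y, spec, seed)
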