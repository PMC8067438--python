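"""Center and center-and-range meta-estimators for interval regression.

Both methods reduce interval-valued regression to point regression:

* **Center method (CM)** — fit one base regressor f on the interval
  midpoints (X^c, y^c) and predict the bounds by evaluating f at the
  endpoint vectors: ``yhat_L = f(X^L)``, ``yhat_U = f(X^U)``.
* **Center-and-range method (CRM)** — fit one base regressor f_c on the
  midpoints and a second f_r on the half-ranges (X^r, y^r), then
  ``yhat_L = f_c(X^c) - f_r(X^r)`` and ``yhat_U = f_c(X^c) + f_r(X^r)``.

Neither rule can guarantee ``yhat_L <= yhat_U``: CM may invert the bounds
wherever the fitted function is decreasing, CRM wherever the predicted
half-range is negative.  Predictions are returned as computed and flagged,
never reordered.

The base regressor is any scikit-learn-style point regressor; the
prediction rules above are family-independent.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .core import IntervalFrame, IntervalValidationError, to_center, to_endpoints, to_halfrange
from .regressors import RegressorSpec, make_regressor

__all__ = [
    "IntervalPrediction",
    "CenterMethodRegressor",
    "CenterRangeMethodRegressor",
    "fit_cm",
    "predict_cm",
    "fit_crm",
    "predict_crm",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


@dataclass
class IntervalPrediction:
    """Predicted intervals, possibly reversed.

    ``values[i] = (yhat_L[i], yhat_U[i])`` as computed by the method;
    ``reversed_flags[i]`` is True iff ``yhat_L[i] > yhat_U[i]``.
    """

    values: np.ndarray
    reversed_flags: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.reversed_flags = np.asarray(self.reversed_flags, dtype=bool)

    @property
    def lower(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def upper(self) -> np.ndarray:
        return self.values[:, 1]

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_frame(self, row_ids=None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "yhat_lower": self.values[:, 0],
                "yhat_upper": self.values[:, 1],
                "reversed_flag": self.reversed_flags,
            },
            index=pd.Index(row_ids if row_ids is not None else range(len(self)), name="id"),
        )


def _frame_matrixes(X) -> tuple:
    """Accept IntervalFrame or (n, p, 2) array; return values + names."""
    if isinstance(X, IntervalFrame):
        return X, list(X.variable_names)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 3 or arr.shape[-1] != 2:
        raise IntervalValidationError(
            f"expected IntervalFrame or (n, p, 2) array, got shape {arr.shape}"
        )
    return IntervalFrame(arr), [f"X{j + 1}" for j in range(arr.shape[1])]


def _response_values(y) -> np.ndarray:
    arr = y.values if hasattr(y, "values") else np.asarray(y, dtype=float)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise IntervalValidationError(f"expected (n, 2) interval response, got {arr.shape}")
    return arr


class _IntervalRegressorBase(RegressorMixin, BaseEstimator):
    def _check_X(self, X) -> IntervalFrame:
        frame, names = _frame_matrixes(X)
        if names != self.variable_names_:
            raise ValueError(
                f"variable mismatch: model trained on {self.variable_names_}, got {names}"
            )
        return frame

    def score(self, X, y):
        """Mean of the lower- and upper-bound squared correlations."""
        from .metrics import interval_r2

        r2l, r2u = interval_r2(_response_values(y), self.predict(X))
        return float(np.nanmean([r2l, r2u]))


class CenterMethodRegressor(_IntervalRegressorBase):
    """Interval regression by the center method over any base regressor.

    Parameters
    ----------
    base : str, RegressorSpec, or estimator, default "lm"
        Base point-regressor family (see :mod:`intervalreg.regressors`).
    random_state : int, optional
        Seed for any internal randomness of the base learner; ignored if
        the spec carries its own seed.

    Attributes
    ----------
    center_model_ : fitted point regressor trained on (X^c, y^c).
    variable_names_ : training column order.
    """

    def __init__(self, base="lm", random_state: int | None = None):
        self.base = base
        self.random_state = random_state

    def fit(self, X, y):
        frame, names = _frame_matrixes(X)
        yv = _response_values(y)
        if len(frame) != yv.shape[0]:
            raise ValueError(f"X has {len(frame)} rows, y has {yv.shape[0]}")
        self.variable_names_ = names
        self.center_model_ = make_regressor(self.base, seed=self.random_state)
        self.center_model_.fit(to_center(frame), to_center(yv))
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted (yhat_L, yhat_U) as an (m, 2) array, unconstrained."""
        frame = self._check_X(X)
        xl, xu = to_endpoints(frame)
        return np.column_stack(
            [self.center_model_.predict(xl), self.center_model_.predict(xu)]
        )

    def predict_interval(self, X) -> IntervalPrediction:
        values = self.predict(X)
        return IntervalPrediction(values, values[:, 0] > values[:, 1])


class CenterRangeMethodRegressor(_IntervalRegressorBase):
    """Interval regression by the center-and-range method.

    Two base regressors are fitted: ``center_model_`` on the midpoints and
    ``range_model_`` on the half-ranges.  Hyperparameter selection (penalty
    path, K, ...) runs independently in each, since they are separate
    regressions.  ``range_base=None`` reuses the center family.

    A negative predicted half-range produces a reversed interval; the
    prediction is returned as computed with its flag set.
    """

    def __init__(self, base="lm", range_base=None, random_state: int | None = None):
        self.base = base
        self.range_base = range_base
        self.random_state = random_state

    def fit(self, X, y):
        frame, names = _frame_matrixes(X)
        yv = _response_values(y)
        if len(frame) != yv.shape[0]:
            raise ValueError(f"X has {len(frame)} rows, y has {yv.shape[0]}")
        self.variable_names_ = names
        seed_c, seed_r = _child_seeds(self.random_state)
        range_base = self.range_base if self.range_base is not None else self.base
        self.center_model_ = make_regressor(self.base, seed=seed_c)
        self.range_model_ = make_regressor(range_base, seed=seed_r)
        self.center_model_.fit(to_center(frame), to_center(yv))
        self.range_model_.fit(to_halfrange(frame), to_halfrange(yv))
        return self

    def predict_components(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(yhat_c, yhat_r): predicted midpoints and half-ranges."""
        frame = self._check_X(X)
        yc = self.center_model_.predict(to_center(frame))
        yr = self.range_model_.predict(to_halfrange(frame))
        return np.asarray(yc, dtype=float), np.asarray(yr, dtype=float)

    def predict(self, X) -> np.ndarray:
        yc, yr = self.predict_components(X)
        return np.column_stack([yc - yr, yc + yr])

    def predict_interval(self, X) -> IntervalPrediction:
        yc, yr = self.predict_components(X)
        return IntervalPrediction(np.column_stack([yc - yr, yc + yr]), yr < 0)


def _child_seeds(random_state: int | None) -> tuple[int | None, int | None]:
    if random_state is None:
        return None, None
    ss = np.random.SeedSequence(random_state)
    a, b = ss.spawn(2)
    return (
        int(a.generate_state(1)[0] % (2**31)),
        int(b.generate_state(1)[0] % (2**31)),
    )


# -- thin functional wrappers ---------------------------------------------


def fit_cm(X, y, spec="lm", seed: int | None = None) -> CenterMethodRegressor:
    """Fit the center method with the given base-regressor spec."""
    return CenterMethodRegressor(base=spec, random_state=seed).fit(X, y)


def predict_cm(model: CenterMethodRegressor, X) -> IntervalPrediction:
    return model.predict_interval(X)


def fit_crm(
    X, y, spec_center="lm", spec_range=None, seed: int | None = None
) -> CenterRangeMethodRegressor:
    """Fit the center-and-range method (range spec defaults to the center's)."""
    return CenterRangeMethodRegressor(
        base=spec_center, range_base=spec_range, random_state=seed
    ).fit(X, y)


def predict_crm(model: CenterRangeMethodRegressor, X) -> IntervalPrediction:
    return model.predict_interval(X)


def save_model(model, path) -> None:
    """Serialize a fitted CM/CRM model to a versioned file."""
    payload = {"format_version": _FORMAT_VERSION, "model": model}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    version = payload.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {version!r}")
    return payload["model"]
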