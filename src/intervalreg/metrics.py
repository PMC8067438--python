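"""Interval regression error metrics.

Performance is measured separately on the lower and upper bounds:

* ``RMSE_L = sqrt(mean((y_L - yhat_L)^2))`` and likewise ``RMSE_U``;
* ``r2_L`` / ``r2_U``: squared Pearson correlation between the true and
  predicted bound, ``(Cov(y, yhat) / (S_y * S_yhat))^2``.

The correlation is undefined whenever a standard deviation is zero
(e.g., a tree predicting one constant); it is reported as NA.  Covariance
and standard deviations use the population (divide-by-n) normalization —
the choice cancels in the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricsRow",
    "interval_rmse",
    "interval_r2",
    "metrics_row",
    "metrics_table",
    "render_tsv",
    "render_markdown",
]

METRIC_COLUMNS = ["RMSE_L", "RMSE_U", "r2_L", "r2_U"]


def _bounds(x) -> tuple[np.ndarray, np.ndarray]:
    arr = x.values if hasattr(x, "values") else np.asarray(x, dtype=float)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected (n, 2) interval values, got shape {arr.shape}")
    return arr[:, 0], arr[:, 1]


def _check_lengths(y, yhat) -> None:
    if len(y[0]) != len(yhat[0]):
        raise ValueError(f"length mismatch: {len(y[0])} true vs {len(yhat[0])} predicted")


def interval_rmse(y, yhat) -> tuple[float, float]:
    """(RMSE_L, RMSE_U) of an interval prediction."""
    yl, yu = _bounds(y)
    pl, pu = _bounds(yhat)
    _check_lengths((yl,), (pl,))
    return (
        float(np.sqrt(np.mean((yl - pl) ** 2))),
        float(np.sqrt(np.mean((yu - pu) ** 2))),
    )


def _r2_one(a: np.ndarray, b: np.ndarray) -> float:
    sa = a.std()
    sb = b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    r = cov / (sa * sb)
    return float(min(r * r, 1.0))


def interval_r2(y, yhat) -> tuple[float, float]:
    """(r2_L, r2_U); NaN marks an undefined (zero-variance) correlation."""
    yl, yu = _bounds(y)
    pl, pu = _bounds(yhat)
    _check_lengths((yl,), (pl,))
    if len(yl) < 2:
        warnings.warn("r2 undefined for n < 2", stacklevel=2)
        return float("nan"), float("nan")
    return _r2_one(yl, pl), _r2_one(yu, pu)


@dataclass
class MetricsRow:
    """One method's scores: (RMSE_L, RMSE_U, r2_L, r2_U), r2 possibly NA."""

    method_label: str
    rmse_l: float
    rmse_u: float
    r2_l: float
    r2_u: float

    def as_list(self) -> list[float]:
        return [self.rmse_l, self.rmse_u, self.r2_l, self.r2_u]


def metrics_row(y, yhat, label: str = "") -> MetricsRow:
    rl, ru = interval_rmse(y, yhat)
    cl, cu = interval_r2(y, yhat)
    return MetricsRow(label, rl, ru, cl, cu)


def metrics_table(rows: list[MetricsRow]) -> pd.DataFrame:
    """Rows stacked into a table with the standard column order."""
    return pd.DataFrame(
        [r.as_list() for r in rows],
        index=pd.Index([r.method_label for r in rows], name="Method"),
        columns=METRIC_COLUMNS,
    )


def render_tsv(table: pd.DataFrame, digits: int = 4) -> str:
    return table.round(digits).to_csv(sep="\t", na_rep="NA")


def render_markdown(table: pd.DataFrame, digits: int = 4) -> str:
    """Plain Markdown table; NaN rendered exactly as 'NA'."""
    header = [table.index.name or "Method", *table.columns]
    lines = [
        "| " + " | ".join(header) + " |",
        "|" + "|".join(["---"] * len(header)) + "|",
    ]
    for label, row in table.iterrows():
        cells = [str(label)]
        for v in row:
            if isinstance(v, float) and np.isnan(v):
                cells.append("NA")
            elif isinstance(v, float):
                cells.append(f"{v:.{digits}f}")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
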