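"""Interval data model: containers, center/half-range/endpoint transforms, CSV I/O.

An interval-valued observation is a closed interval ``[a, b]`` with
``a <= b``.  A dataset is a rectangular grid of such intervals
(:class:`IntervalFrame`) together with an interval-valued response
(:class:`IntervalVector`).  All downstream regression methods operate on
real-valued views of this data:

* centers (midpoints)      ``x^c = (a + b) / 2``
* half-ranges              ``x^r = (b - a) / 2``
* endpoints                ``x^L = a``, ``x^U = b``

Storage is a float64 array of shape ``(n, p, 2)`` (or ``(n, 2)`` for a
vector), last axis ordered (lower, upper).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "IntervalFrame",
    "IntervalVector",
    "IntervalSchemaError",
    "IntervalValidationError",
    "to_center",
    "to_halfrange",
    "to_endpoints",
    "read_interval_csv",
    "write_interval_csv",
]


class IntervalSchemaError(ValueError):
    """A CSV file does not follow the paired lower/upper column dialect."""


class IntervalValidationError(ValueError):
    """Ingested interval data violates ``lower <= upper`` or shape rules."""


@dataclass(frozen=True)
class Interval:
    """A closed real interval ``[lower, upper]``."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise IntervalValidationError(f"non-finite interval [{self.lower}, {self.upper}]")
        if self.lower > self.upper:
            raise IntervalValidationError(
                f"interval lower bound {self.lower} exceeds upper bound {self.upper}"
            )

    @property
    def center(self) -> float:
        return (self.lower + self.upper) / 2.0

    @property
    def half_range(self) -> float:
        return (self.upper - self.lower) / 2.0

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _validate_bounds(values: np.ndarray, names: Sequence[str]) -> None:
    if not np.all(np.isfinite(values)):
        raise IntervalValidationError("interval data contains non-finite entries")
    bad = values[..., 0] > values[..., 1]
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        if idx.size == 2:
            i, j = idx
            raise IntervalValidationError(
                f"row {i}, variable {names[j]!r}: lower bound "
                f"{values[i, j, 0]} exceeds upper bound {values[i, j, 1]}"
            )
        i = idx[0]
        raise IntervalValidationError(
            f"row {i}, variable {names[0]!r}: lower bound "
            f"{values[i, 0]} exceeds upper bound {values[i, 1]}"
        )


class IntervalFrame:
    """An ``n x p`` grid of intervals with variable names and row ids."""

    def __init__(
        self,
        values: np.ndarray,
        variable_names: Sequence[str] | None = None,
        row_ids: Sequence | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 3 or values.shape[2] != 2:
            raise IntervalValidationError(
                f"expected shape (n, p, 2), got {values.shape}"
            )
        n, p, _ = values.shape
        if n < 1 or p < 1:
            raise IntervalValidationError("IntervalFrame requires n >= 1 and p >= 1")
        if variable_names is None:
            variable_names = [f"X{j + 1}" for j in range(p)]
        variable_names = [str(v) for v in variable_names]
        if len(variable_names) != p:
            raise IntervalValidationError(
                f"{len(variable_names)} variable names for p={p} columns"
            )
        if row_ids is None:
            row_ids = list(range(n))
        row_ids = list(row_ids)
        if len(row_ids) != n:
            raise IntervalValidationError(f"{len(row_ids)} row ids for n={n} rows")
        _validate_bounds(values, variable_names)
        self.values = values
        self.variable_names = variable_names
        self.row_ids = row_ids

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        lower: np.ndarray,
        upper: np.ndarray,
        variable_names: Sequence[str] | None = None,
        row_ids: Sequence | None = None,
    ) -> "IntervalFrame":
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        if lower.shape != upper.shape or lower.ndim != 2:
            raise IntervalValidationError("lower/upper must be equal-shape 2-D arrays")
        return cls(np.stack([lower, upper], axis=-1), variable_names, row_ids)

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[0], self.values.shape[1]

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, key) -> Interval:
        i, j = key
        return Interval(self.values[i, j, 0], self.values[i, j, 1])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IntervalFrame)
            and self.variable_names == other.variable_names
            and self.row_ids == other.row_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        n, p = self.shape
        return f"IntervalFrame(n={n}, p={p}, variables={self.variable_names})"

    def take(self, indices: Iterable[int]) -> "IntervalFrame":
        """Row subset (used by the evaluation harness for splits/folds)."""
        indices = np.asarray(list(indices), dtype=int)
        return IntervalFrame(
            self.values[indices],
            self.variable_names,
            [self.row_ids[i] for i in indices],
        )

    # -- numeric views ----------------------------------------------------
    @property
    def lower(self) -> np.ndarray:
        return self.values[..., 0]

    @property
    def upper(self) -> np.ndarray:
        return self.values[..., 1]

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        for j, name in enumerate(self.variable_names):
            cols[f"{name}.lower"] = self.values[:, j, 0]
            cols[f"{name}.upper"] = self.values[:, j, 1]
        return pd.DataFrame(cols, index=pd.Index(self.row_ids, name="id"))


class IntervalVector:
    """A length-``n`` sequence of intervals (typically the response)."""

    def __init__(self, values: np.ndarray, name: str = "Y") -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 2:
            raise IntervalValidationError(f"expected shape (n, 2), got {values.shape}")
        if values.shape[0] < 1:
            raise IntervalValidationError("IntervalVector requires n >= 1")
        _validate_bounds(values, [name])
        self.values = values
        self.name = str(name)

    @property
    def lower(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def upper(self) -> np.ndarray:
        return self.values[:, 1]

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, i: int) -> Interval:
        return Interval(self.values[i, 0], self.values[i, 1])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IntervalVector)
            and self.name == other.name
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"IntervalVector(n={len(self)}, name={self.name!r})"

    def take(self, indices: Iterable[int]) -> "IntervalVector":
        indices = np.asarray(list(indices), dtype=int)
        return IntervalVector(self.values[indices], self.name)


def _interval_values(x) -> np.ndarray:
    """Raw (..., 2) float array behind a frame, vector, or array-like."""
    if isinstance(x, (IntervalFrame, IntervalVector)):
        return x.values
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0 or arr.shape[-1] != 2:
        raise IntervalValidationError(
            f"cannot interpret shape {arr.shape} as interval data"
        )
    return arr


def to_center(x) -> np.ndarray:
    """Elementwise midpoints ``(a + b) / 2``; shape ``(n, p)`` or ``(n,)``."""
    v = _interval_values(x)
    return (v[..., 0] + v[..., 1]) / 2.0


def to_halfrange(x) -> np.ndarray:
    """Elementwise half-widths ``(b - a) / 2``; nonnegative on valid data."""
    v = _interval_values(x)
    return (v[..., 1] - v[..., 0]) / 2.0


def to_endpoints(x) -> tuple[np.ndarray, np.ndarray]:
    """The pair of real matrices (all lower bounds, all upper bounds)."""
    v = _interval_values(x)
    return v[..., 0].copy(), v[..., 1].copy()


# -- CSV dialect ----------------------------------------------------------
#
# One header row; each interval variable V contributes two columns,
# "V.lower" then "V.upper"; UTF-8; '.' decimal separator.  An optional
# leading "id" column carries row ids.

def _paired_variables(columns: Sequence[str]) -> list[str]:
    names: list[str] = []
    for col in columns:
        if col.endswith(".lower"):
            names.append(col[: -len(".lower")])
    for name in names:
        if f"{name}.upper" not in columns:
            raise IntervalSchemaError(f"missing column {name + '.upper'!r}")
    for col in columns:
        if col == "id":
            continue
        if not (col.endswith(".lower") or col.endswith(".upper")):
            raise IntervalSchemaError(
                f"column {col!r} does not follow the 'V.lower'/'V.upper' dialect"
            )
        if col.endswith(".upper") and col[: -len(".upper")] not in names:
            raise IntervalSchemaError(f"missing column {col[: -len('.upper')] + '.lower'!r}")
    return names


def read_interval_csv(
    path, response: str | None = None
) -> tuple[IntervalFrame, IntervalVector | None]:
    """Read an interval CSV; returns (predictors, response).

    Parameters
    ----------
    path : path-like
        CSV file in the paired-column dialect.
    response : str, optional
        Name of the response variable.  Its pair of columns is split off
        into the returned :class:`IntervalVector`.  With ``response=None``
        all variables land in the frame and the second element is None.

    Raises
    ------
    IntervalSchemaError
        Missing/mispaired columns, or unknown response name.
    IntervalValidationError
        Any row with ``lower > upper``, or non-numeric cells.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    names = _paired_variables(list(df.columns))
    if not names:
        raise IntervalSchemaError("no interval variable columns found")
    row_ids = list(df["id"]) if "id" in df.columns else list(range(len(df)))
    if response is not None and response not in names:
        raise IntervalSchemaError(
            f"response variable {response!r} not among columns (found {names})"
        )

    def pair(name: str) -> np.ndarray:
        sub = df[[f"{name}.lower", f"{name}.upper"]]
        try:
            arr = sub.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise IntervalValidationError(
                f"non-numeric cell in variable {name!r}: {exc}"
            ) from exc
        return arr

    predictors = [n for n in names if n != response]
    if not predictors:
        raise IntervalSchemaError("no predictor variables besides the response")
    stacked = np.stack([pair(n) for n in predictors], axis=1)
    frame = IntervalFrame(stacked, predictors, row_ids)
    vector = None
    if response is not None:
        vector = IntervalVector(pair(response), response)
    return frame, vector


def write_interval_csv(
    frame: IntervalFrame, vector: IntervalVector | None, path
) -> None:
    """Write predictors (and optionally the response) in the paired dialect.

    Column order is deterministic: frame variables in order, each lower
    before upper, response last.
    """
    if len(frame) < 1:
        raise IntervalValidationError("cannot write an empty frame")
    df = frame.to_dataframe()
    if vector is not None:
        if len(vector) != len(frame):
            raise IntervalValidationError("frame and response lengths differ")
        df[f"{vector.name}.lower"] = vector.lower
        df[f"{vector.name}.upper"] = vector.upper
    df.to_csv(path, index=True)
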