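"""Experiment harness: holdout and K-fold CV over a roster of methods.

A *roster* is a list of labelled (mode, base-family) entries, e.g.
``("KNN CRM", "CRM", RegressorSpec("knn"))``.  The default roster crosses
the nine base families with the two interval methods, in the benchmark
table order (all CM rows, then all CRM rows).

Every method in a run is evaluated on identical splits or folds.  All
randomness (the split, the fold deal, and each base learner's internal
seed) derives from one master seed, so an entire benchmark is
reproducible from a single integer.  A method that fails to fit (e.g.,
an ensemble on a table too short for it) is recorded as a row of NA with
the failure message; the run continues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import IntervalFrame, IntervalVector, read_interval_csv
from .methods import CenterMethodRegressor, CenterRangeMethodRegressor
from .metrics import METRIC_COLUMNS, metrics_row, metrics_table, render_markdown, render_tsv
from .regressors import RegressorSpec
from .simulate import D_CONFIGS, simulate

__all__ = [
    "MethodEntry",
    "MethodRoster",
    "CVResult",
    "default_roster",
    "holdout_eval",
    "kfold_eval",
    "benchmark",
]

FAMILY_LABELS = [
    ("LM", "lm"),
    ("Ridge", "ridge"),
    ("Lasso", "lasso"),
    ("RT", "tree"),
    ("RF", "rf"),
    ("Boost", "boost"),
    ("KNN", "knn"),
    ("SVM", "svm"),
    ("NNet", "nnet"),
]


@dataclass
class MethodEntry:
    label: str
    mode: str  # "CM" or "CRM"
    spec: RegressorSpec

    def __post_init__(self) -> None:
        if self.mode not in ("CM", "CRM"):
            raise ValueError(f"mode must be 'CM' or 'CRM', got {self.mode!r}")

    def build(self, seed: int | None):
        if self.mode == "CM":
            return CenterMethodRegressor(base=self.spec, random_state=seed)
        return CenterRangeMethodRegressor(base=self.spec, random_state=seed)


@dataclass
class MethodRoster:
    entries: list[MethodEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("roster labels must be unique")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]


def default_roster(families: list[str] | None = None) -> MethodRoster:
    """The benchmark roster: each family under CM, then under CRM."""
    chosen = [(lab, fam) for lab, fam in FAMILY_LABELS if families is None or fam in families]
    entries = [
        MethodEntry(f"{lab} {mode}", mode, RegressorSpec(fam))
        for mode in ("CM", "CRM")
        for lab, fam in chosen
    ]
    return MethodRoster(entries)


@dataclass
class CVResult:
    """K-fold result: per-fold rows plus fold-mean and fold-sd tables."""

    per_fold: pd.DataFrame  # columns: fold, Method, RMSE_L, RMSE_U, r2_L, r2_U
    mean_table: pd.DataFrame
    sd_table: pd.DataFrame
    fold_assignment: np.ndarray
    seed: int | None
    failures: dict[str, str] = field(default_factory=dict)


def _method_seeds(seed: int | None, n_methods: int) -> tuple[int, list[int | None]]:
    """Master seed -> (split seed, one child seed per roster entry)."""
    if seed is None:
        return None, [None] * n_methods
    children = np.random.SeedSequence(seed).spawn(n_methods + 1)
    ints = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    return ints[0], ints[1:]


def _coerce_roster(roster) -> MethodRoster:
    if roster is None:
        return default_roster()
    if isinstance(roster, MethodRoster):
        return roster
    return MethodRoster(list(roster))


def _score_entry(entry, X_train, y_train, X_test, y_test, seed):
    model = entry.build(seed)
    model.fit(X_train, y_train)
    pred = model.predict_interval(X_test)
    return metrics_row(y_test, pred, entry.label)


def holdout_eval(
    X: IntervalFrame,
    y: IntervalVector,
    roster=None,
    train_fraction: float = 0.7,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """One shared random train/test split; returns (table, failures).

    The training set holds ``floor(train_fraction * n)`` rows.  Failed
    methods appear as NA rows with their message in ``failures``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = len(X)
    n_train = int(np.floor(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError(f"degenerate split: {n_train} train of {n} rows")
    roster = _coerce_roster(roster)
    split_seed, seeds = _method_seeds(seed, len(roster))
    perm = np.random.default_rng(split_seed).permutation(n)
    train_idx, test_idx = perm[:n_train], perm[n_train:]

    rows, failures = [], {}
    Xtr, ytr = X.take(train_idx), y.take(train_idx)
    Xte, yte = X.take(test_idx), y.take(test_idx)
    for entry, s in zip(roster, seeds):
        try:
            rows.append(_score_entry(entry, Xtr, ytr, Xte, yte, s))
        except Exception as exc:  # keep the run alive; report the row as failed
            failures[entry.label] = str(exc)
            rows.append(metrics_row_nan(entry.label))
    return metrics_table(rows), failures


def metrics_row_nan(label: str):
    from .metrics import MetricsRow

    nan = float("nan")
    return MetricsRow(label, nan, nan, nan, nan)


def fold_indices(n: int, k: int, seed: int | None) -> np.ndarray:
    """Deal rows into k near-equal folds after one seeded permutation."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} rows")
    perm = np.random.default_rng(seed).permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = f
    return assignment


def kfold_eval(
    X: IntervalFrame,
    y: IntervalVector,
    roster=None,
    k: int = 10,
    seed: int | None = None,
) -> CVResult:
    """K-fold cross-validation with identical folds for every method.

    Metrics are computed per fold and then averaged (not pooled); the sd
    table uses the n-1 denominator across folds.
    """
    roster = _coerce_roster(roster)
    n = len(X)
    split_seed, seeds = _method_seeds(seed, len(roster))
    assignment = fold_indices(n, k, split_seed)

    records = []
    failures: dict[str, str] = {}
    for f in range(k):
        test_idx = np.where(assignment == f)[0]
        train_idx = np.where(assignment != f)[0]
        Xtr, ytr = X.take(train_idx), y.take(train_idx)
        Xte, yte = X.take(test_idx), y.take(test_idx)
        for entry, s in zip(roster, seeds):
            if entry.label in failures:
                continue
            try:
                row = _score_entry(entry, Xtr, ytr, Xte, yte, s)
            except Exception as exc:
                failures[entry.label] = f"fold {f}: {exc}"
                continue
            records.append({"fold": f, "Method": entry.label, **dict(zip(METRIC_COLUMNS, row.as_list()))})

    per_fold = pd.DataFrame.from_records(records)
    ok_labels = [lab for lab in roster.labels if lab not in failures]
    if per_fold.empty:
        grouped = pd.DataFrame(columns=METRIC_COLUMNS)
        mean_table = grouped
        sd_table = grouped
    else:
        per_fold = per_fold[~per_fold["Method"].isin(failures)]
        g = per_fold.groupby("Method", sort=False)[METRIC_COLUMNS]
        mean_table = g.mean().reindex(ok_labels)
        sd_table = g.std(ddof=1).reindex(ok_labels)
    # failed methods: NA rows at their roster position
    if failures:
        nan_row = {c: float("nan") for c in METRIC_COLUMNS}
        for lab in failures:
            mean_table.loc[lab] = nan_row
            sd_table.loc[lab] = nan_row
        mean_table = mean_table.reindex(roster.labels)
        sd_table = sd_table.reindex(roster.labels)
    mean_table.index.name = sd_table.index.name = "Method"
    return CVResult(per_fold, mean_table, sd_table, assignment, seed, failures)


# -------------------------------------------------------------------------
# Benchmark orchestration
# -------------------------------------------------------------------------


def _table_records(table: pd.DataFrame) -> list[dict[str, Any]]:
    recs = []
    for label, row in table.iterrows():
        rec: dict[str, Any] = {"Method": str(label)}
        for c in METRIC_COLUMNS:
            v = float(row[c])
            rec[c] = None if np.isnan(v) else v
        recs.append(rec)
    return recs


def _records_frame(records: list[dict[str, Any]]) -> pd.DataFrame:
    df = pd.DataFrame.from_records(records).set_index("Method")
    return df[METRIC_COLUMNS].astype(float)


def benchmark(
    design: str | None = None,
    data: str | Path | None = None,
    response: str | None = None,
    roster=None,
    mode: str = "holdout",
    k: int = 10,
    train_fraction: float = 0.7,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    sim_overrides: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Run one full experiment and return (and optionally write) a report.

    Either ``design`` (one of D1-D4 or 'nonlinear') or ``data`` (an
    interval CSV path, with ``response`` naming the response variable)
    must be given.  ``mode`` is 'holdout' or 'cv'.  The report dict holds
    every number; ``out_dir`` additionally gets results.json, TSV and
    Markdown tables, and the resolved configuration.
    """
    if (design is None) == (data is None):
        raise ValueError("give exactly one of design= or data=")
    if mode not in ("holdout", "cv"):
        raise ValueError(f"mode must be 'holdout' or 'cv', got {mode!r}")
    roster = _coerce_roster(roster)

    # distinct child seeds for data generation and for the evaluation split
    if seed is None:
        sim_seed = eval_seed = None
    else:
        children = np.random.SeedSequence(seed).spawn(2)
        sim_seed, eval_seed = (int(c.generate_state(1)[0] % (2**31)) for c in children)

    if design is not None:
        valid = [*D_CONFIGS, "nonlinear"]
        if design not in valid:
            raise ValueError(f"unknown design {design!r}; valid: {', '.join(valid)}")
        result = simulate(design, seed=sim_seed, **(sim_overrides or {}))
        X, y = result.X, result.y
        source: dict[str, Any] = {"design": design, "truth": result.truth}
    else:
        X, y = read_interval_csv(data, response=response)
        if y is None:
            raise ValueError("data= requires response= naming the response variable")
        source = {"data": str(data), "response": response}

    report: dict[str, Any] = {
        "config": {
            "mode": mode,
            "k": k if mode == "cv" else None,
            "train_fraction": train_fraction if mode == "holdout" else None,
            "seed": seed,
            "roster": [
                {"label": e.label, "mode": e.mode, "spec": e.spec.to_dict()} for e in roster
            ],
        },
        "source": source,
        "n": len(X),
        "p": X.shape[1],
    }
    if mode == "holdout":
        table, failures = holdout_eval(X, y, roster, train_fraction, eval_seed)
        report["tables"] = {"metrics": _table_records(table)}
        report["failures"] = failures
    else:
        cv = kfold_eval(X, y, roster, k=k, seed=eval_seed)
        report["tables"] = {
            "mean": _table_records(cv.mean_table),
            "sd": _table_records(cv.sd_table),
        }
        report["failures"] = cv.failures
        report["fold_sizes"] = np.bincount(cv.fold_assignment, minlength=k).tolist()

    if out_dir is not None:
        write_report(report, out_dir)
    return report


def render_report_tables(report: dict[str, Any]) -> dict[str, dict[str, str]]:
    """TSV and Markdown renderings of every table in a report dict."""
    out: dict[str, dict[str, str]] = {}
    for name, records in report["tables"].items():
        table = _records_frame(records)
        out[name] = {"tsv": render_tsv(table), "markdown": render_markdown(table)}
    return out


def write_report(report: dict[str, Any], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    for name, rendered in render_report_tables(report).items():
        (out / f"table_{name}.tsv").write_text(rendered["tsv"], encoding="utf-8")
        (out / f"table_{name}.md").write_text(rendered["markdown"], encoding="utf-8")
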