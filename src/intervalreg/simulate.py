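"""Monte Carlo generators for synthetic interval-valued datasets.

Two designs are provided.

**Linear (configurations D1-D4).**  375 rows, 3 interval predictors.
Midpoints ``X_j^c ~ U[20, 40]``; the response midpoint follows
``Y^c = beta_0 + sum_j beta_j X_j^c + eps`` with ``beta ~ U[-10, 10]`` and
uniform noise ``eps``.  Half-ranges are linearly tied to the midpoints:
``Y^r = Y^c b* + eps*`` and ``X_j^r = X_j^c b*_j + eps*`` with
``b* ~ U[0.5, 1.5]`` (independent draw per relation) and uniform noise
``eps*``.  The four named configurations cross midpoint-noise level with
midpoint-range dependence strength:

====  ================  ===============
name  eps bounds        eps* bounds
D1    U[-20, 20]        U[1, 5]
D2    U[-20, 20]        U[10, 20]
D3    U[-5, 5]          U[1, 5]
D4    U[-5, 5]          U[10, 20]
====  ================  ===============

**Nonlinear.**  3000 rows, 3 interval predictors.  Midpoints
``X_j^c ~ U[-6, 6]`` with a logistic response midpoint

    Y_i^c = th0c / (th1c + exp(th2c X_1i^c + ... + th(p+1)c X_pi^c)) + eps_i^c

where ``th0c ~ U[1.9, 2.1]``, ``th1c ~ U[2.9, 3.1]``,
``thmc ~ U[0.9, 1.1]`` and ``eps^c ~ Normal(0, sd=0.05)``.  Half-ranges
``X_j^r ~ U[1, 4]`` with an exponential response half-range

    Y_i^r = th0r + exp(-(th1r X_1i^r + ... + thpr X_pi^r)) + eps_i^r

where ``th0r ~ U[0, 0.5]``, ``thmr ~ U[0.9, 1.1]`` and
``eps^r ~ Normal(0, sd=0.01)``.  Coefficients are drawn once per dataset.

Both generators assemble intervals as ``[c - r, c + r]``.  A simulated
half-range can come out negative (the response midpoint may be negative
while its noise is positive); such values are clipped to 0 and counted in
the truth record, so the repair is visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import IntervalFrame, IntervalVector, write_interval_csv

__all__ = [
    "D_CONFIGS",
    "LinearSimConfig",
    "NonlinearSimConfig",
    "SimResult",
    "simulate_linear",
    "simulate_nonlinear",
    "simulate",
    "write_sim_result",
]

# name -> (center-noise bounds, range-noise bounds)
D_CONFIGS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "D1": ((-20.0, 20.0), (1.0, 5.0)),
    "D2": ((-20.0, 20.0), (10.0, 20.0)),
    "D3": ((-5.0, 5.0), (1.0, 5.0)),
    "D4": ((-5.0, 5.0), (10.0, 20.0)),
}


def _check_bounds(b, label: str) -> tuple[float, float]:
    lo, hi = float(b[0]), float(b[1])
    if lo > hi:
        raise ValueError(f"invalid {label} bounds: [{lo}, {hi}]")
    return lo, hi


@dataclass
class LinearSimConfig:
    """Configuration of the linear midpoint/half-range design.

    ``design`` picks the named noise bounds; explicit ``center_noise`` /
    ``range_noise`` override them.  ``shared_dependence=True`` uses one
    b* draw for all midpoint-range relations instead of one per relation.
    """

    design: str | None = "D1"
    n: int = 375
    n_train: int = 250
    p: int = 3
    center_noise: tuple[float, float] | None = None
    range_noise: tuple[float, float] | None = None
    shared_dependence: bool = False
    seed: int | None = None

    def noise_bounds(self) -> tuple[tuple[float, float], tuple[float, float]]:
        if self.design is not None:
            if self.design not in D_CONFIGS:
                raise ValueError(
                    f"unknown design {self.design!r}; valid: {', '.join(D_CONFIGS)}"
                )
            center, rng = D_CONFIGS[self.design]
        else:
            if self.center_noise is None or self.range_noise is None:
                raise ValueError("custom configs need center_noise and range_noise")
            center, rng = self.center_noise, self.range_noise
        if self.center_noise is not None:
            center = self.center_noise
        if self.range_noise is not None:
            rng = self.range_noise
        return _check_bounds(center, "center-noise"), _check_bounds(rng, "range-noise")


@dataclass
class NonlinearSimConfig:
    n: int = 3000
    p: int = 3
    center_noise_sd: float = 0.05
    range_noise_sd: float = 0.01
    seed: int | None = None


@dataclass
class SimResult:
    """Generated dataset plus the ground truth that produced it."""

    X: IntervalFrame
    y: IntervalVector
    truth: dict[str, Any] = field(default_factory=dict)


def simulate_linear(config: LinearSimConfig) -> SimResult:
    """Generate one dataset from the linear design."""
    (a, b), (i_lo, j_hi) = config.noise_bounds()
    n, p = config.n, config.p
    if n < 1 or p < 1:
        raise ValueError("n and p must be positive")
    rng = np.random.default_rng(config.seed)

    xc = rng.uniform(20.0, 40.0, size=(n, p))
    beta = rng.uniform(-10.0, 10.0, size=p + 1)
    yc = beta[0] + xc @ beta[1:] + rng.uniform(a, b, size=n)

    n_rel = 1 if config.shared_dependence else p + 1
    bstar = rng.uniform(0.5, 1.5, size=n_rel)
    if config.shared_dependence:
        bstar = np.repeat(bstar, p + 1)
    yr = yc * bstar[0] + rng.uniform(i_lo, j_hi, size=n)
    xr = xc * bstar[1:] + rng.uniform(i_lo, j_hi, size=(n, p))

    clipped_y = int(np.sum(yr < 0))
    clipped_x = int(np.sum(xr < 0))
    yr = np.clip(yr, 0.0, None)
    xr = np.clip(xr, 0.0, None)

    frame = IntervalFrame.from_arrays(xc - xr, xc + xr)
    vector = IntervalVector(np.column_stack([yc - yr, yc + yr]), name="Y")
    truth = {
        "design": config.design,
        "beta": beta.tolist(),
        "beta_star": bstar.tolist(),
        "center_noise": [a, b],
        "range_noise": [i_lo, j_hi],
        "clipped_negative_ranges": {"y": clipped_y, "x": clipped_x},
        "n": n,
        "n_train": config.n_train,
        "p": p,
        "seed": config.seed,
    }
    return SimResult(frame, vector, truth)


def simulate_nonlinear(config: NonlinearSimConfig) -> SimResult:
    """Generate one dataset from the logistic/exponential nonlinear design."""
    n, p = config.n, config.p
    if n < 1 or p < 1:
        raise ValueError("n and p must be positive")
    if config.center_noise_sd < 0 or config.range_noise_sd < 0:
        raise ValueError("noise standard deviations must be nonnegative")
    rng = np.random.default_rng(config.seed)

    xc = rng.uniform(-6.0, 6.0, size=(n, p))
    theta_c = np.concatenate(
        [
            rng.uniform(1.9, 2.1, size=1),
            rng.uniform(2.9, 3.1, size=1),
            rng.uniform(0.9, 1.1, size=p),
        ]
    )
    yc = theta_c[0] / (theta_c[1] + np.exp(xc @ theta_c[2:]))
    yc = yc + rng.normal(0.0, config.center_noise_sd, size=n)

    xr = rng.uniform(1.0, 4.0, size=(n, p))
    theta_r = np.concatenate(
        [rng.uniform(0.0, 0.5, size=1), rng.uniform(0.9, 1.1, size=p)]
    )
    yr = theta_r[0] + np.exp(-(xr @ theta_r[1:]))
    yr = yr + rng.normal(0.0, config.range_noise_sd, size=n)

    clipped = int(np.sum(yr < 0))
    yr = np.clip(yr, 0.0, None)

    frame = IntervalFrame.from_arrays(xc - xr, xc + xr)
    vector = IntervalVector(np.column_stack([yc - yr, yc + yr]), name="Y")
    truth = {
        "design": "nonlinear",
        "theta_c": theta_c.tolist(),
        "theta_r": theta_r.tolist(),
        "center_noise_sd": config.center_noise_sd,
        "range_noise_sd": config.range_noise_sd,
        "clipped_negative_ranges": {"y": clipped},
        "n": n,
        "p": p,
        "seed": config.seed,
    }
    return SimResult(frame, vector, truth)


def simulate(design: str, seed: int | None = None, **overrides) -> SimResult:
    """Generate by design name: one of D1-D4 or 'nonlinear'."""
    if design in D_CONFIGS:
        return simulate_linear(LinearSimConfig(design=design, seed=seed, **overrides))
    if design == "nonlinear":
        return simulate_nonlinear(NonlinearSimConfig(seed=seed, **overrides))
    valid = ", ".join([*D_CONFIGS, "nonlinear"])
    raise ValueError(f"unknown design {design!r}; valid: {valid}")


def write_sim_result(result: SimResult, csv_path, truth_path=None) -> None:
    """Write the interval CSV plus a JSON sidecar with the truth record."""
    write_interval_csv(result.X, result.y, csv_path)
    if truth_path is not None:
        with open(truth_path, "w", encoding="utf-8") as fh:
            json.dump(result.truth, fh, indent=2)
            fh.write("\n")
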