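"""Linear volume-to-body-weight model and its error statistics.

Closed-form simple least squares: a = sum((x-xbar)(y-ybar)) / sum((x-xbar)^2),
b = ybar - a*xbar, with Pearson r and R^2 = 1 - SSR/SST (equal to r^2 for
this model). Error summaries use linearly interpolated quartiles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["WeightModel", "ErrorStats", "fit_weight_model", "predict_weight", "evaluate_errors"]


@dataclass(frozen=True)
class WeightModel:
    """Fitted volume->weight line with diagnostics."""

    a: float  # slope, kg per volume unit
    b: float  # intercept, kg
    r: float  # Pearson correlation
    r_squared: float  # goodness of fit
    n: int  # training count

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r must lie in [-1, 1]")
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "WeightModel":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class ErrorStats:
    """Absolute (kg) and relative (%) error summaries."""

    max_abs: float
    min_abs: float
    mean_abs: float
    q1_abs: float
    q3_abs: float
    max_rel: float
    min_rel: float
    mean_rel: float
    q1_rel: float
    q3_rel: float


def fit_weight_model(volumes, weights) -> WeightModel:
    """Least-squares line through (volume, weight) pairs."""
    x = np.asarray(volumes, dtype=np.float64)
    y = np.asarray(weights, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("volumes and weights must be equal-length 1D sequences")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("volumes have zero variance; slope undefined")
    sxy = float(((x - xbar) * (y - ybar)).sum())
    a = sxy / sxx
    b = ybar - a * xbar
    fitted = a * x + b
    sst = float(((y - ybar) ** 2).sum())
    ssr = float(((y - fitted) ** 2).sum())
    r_squared = 1.0 - ssr / sst if sst > 0 else 1.0
    syy = sst
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 1.0
    return WeightModel(
        a=a,
        b=b,
        r=float(np.clip(r, -1.0, 1.0)),
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        n=n,
    )


def predict_weight(model: WeightModel, volume: float) -> float:
    """Predicted weight (kg): a * volume + b."""
    return model.a * volume + model.b


def evaluate_errors(predicted, actual) -> ErrorStats:
    """Absolute and relative (percent of actual) error summary statistics.

    Quartiles use linear interpolation between order statistics.
    """
    p = np.asarray(predicted, dtype=np.float64)
    t = np.asarray(actual, dtype=np.float64)
    if p.shape != t.shape or p.ndim != 1 or len(p) < 1:
        raise ValueError("predicted and actual must be equal-length 1D sequences")
    if np.any(t <= 0):
        raise ValueError("actual weights must be positive")
    abs_err = np.abs(p - t)
    rel_err = 100.0 * abs_err / t
    q1a, q3a = np.percentile(abs_err, [25, 75])
    q1r, q3r = np.percentile(rel_err, [25, 75])
    return ErrorStats(
        max_abs=float(abs_err.max()),
        min_abs=float(abs_err.min()),
        mean_abs=float(abs_err.mean()),
        q1_abs=float(q1a),
        q3_abs=float(q3a),
        max_rel=float(rel_err.max()),
        min_rel=float(rel_err.min()),
        mean_rel=float(rel_err.mean()),
        q1_rel=float(q1r),
        q3_rel=float(q3r),
    )
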