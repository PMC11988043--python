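"""Regression evaluation metrics for weight estimation.

All three metrics compare estimated weights ``y_hat`` with true weights
``y`` (kg, de-normalised scale):

* MAE  = (1/n) sum |y_hat_i - y_i|
* RMSE = sqrt((1/n) sum (y_hat_i - y_i)^2)
* R2   = 1 - sum (y_hat_i - y_i)^2 / sum (ybar - y_i)^2, ybar = mean(y)

R2 is not clamped: a model worse than the mean predictor yields R2 < 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["mae", "rmse", "r2", "MetricsReport", "compute_report"]


def _validate(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} true vs {y_hat.shape[0]} predicted")
    if y.size == 0:
        raise ValueError("metrics undefined for empty input")
    return y, y_hat


def mae(y, y_hat) -> float:
    """Mean absolute error in kg."""
    y, y_hat = _validate(y, y_hat)
    return float(np.mean(np.abs(y_hat - y)))


def rmse(y, y_hat) -> float:
    """Root-mean-square error in kg."""
    y, y_hat = _validate(y, y_hat)
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


def r2(y, y_hat) -> float:
    """Coefficient of determination against the mean-of-truth predictor."""
    y, y_hat = _validate(y, y_hat)
    if y.size < 2:
        raise ValueError("R^2 requires at least two samples")
    ss_tot = float(np.sum((y.mean() - y) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: true values have zero variance")
    ss_res = float(np.sum((y_hat - y) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class MetricsReport:
    mae: float
    rmse: float
    r2: float
    n: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def __str__(self) -> str:
        return (f"n={self.n}  MAE={self.mae:.4f} kg  "
                f"RMSE={self.rmse:.4f} kg  R2={self.r2:.4f}")


def compute_report(y, y_hat) -> MetricsReport:
    y_arr, _ = _validate(y, y_hat)
    return MetricsReport(mae=mae(y, y_hat), rmse=rmse(y, y_hat),
                         r2=r2(y, y_hat), n=int(y_arr.size))
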