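"""Regression head and training losses.

The head is deliberately minimal: global average pooling followed by a
two-layer perceptron with a ReLU in between and no output activation
(weights are unbounded above).  Losses operate on batches and reduce by
the mean; L1 is the default, matching the MAE evaluation criterion.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["RegressionHead", "WeightPrediction", "l1_loss", "l2_loss",
           "smooth_l1_loss", "make_loss"]

from dataclasses import dataclass


@dataclass(frozen=True)
class WeightPrediction:
    weight_hat: float
    sample_id: str = ""

    def __post_init__(self):
        if not np.isfinite(self.weight_hat):
            raise ValueError(
                f"non-finite prediction for sample {self.sample_id!r}")


class RegressionHead(nn.Module):
    def __init__(self, in_channels: int, hidden: int = 128):
        super().__init__()
        self.fc1 = nn.Linear(in_channels, hidden)
        self.fc2 = nn.Linear(hidden, 1)

    def forward(self, f: Tensor) -> Tensor:
        """(N,C,H,W) feature map -> (N,) weight estimates."""
        if not np.all(np.isfinite(f.data)):
            raise FloatingPointError("non-finite values in regression input")
        pooled = nn.global_avg_pool(f)
        return self.fc2(self.fc1(pooled).relu()).reshape(f.shape[0])


def _as_target(y) -> Tensor:
    return y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=float))


def l1_loss(y_hat: Tensor, y) -> Tensor:
    return (y_hat - _as_target(y)).abs().mean()


def l2_loss(y_hat: Tensor, y) -> Tensor:
    return ((y_hat - _as_target(y)) ** 2.0).mean()


def smooth_l1_loss(y_hat: Tensor, y, beta: float = 1.0) -> Tensor:
    """Quadratic within |r| < beta, linear outside (Huber-style)."""
    r = y_hat - _as_target(y)
    quad_mask = Tensor((np.abs(r.data) < beta).astype(float))
    quadratic = r * r * (0.5 / beta)
    linear = r.abs() - 0.5 * beta
    return (quad_mask * quadratic + (1.0 - quad_mask) * linear).mean()


def make_loss(name: str):
    try:
        return {"l1": l1_loss, "l2": l2_loss, "smooth_l1": smooth_l1_loss}[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}") from None
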