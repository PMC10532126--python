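"""Regression losses and the RMSE evaluation metric.

The training-loss family is MSE, MAE, RMSE and weighted MSE

    WMSE = reduce_i  w * (Y_i - Yhat_i)^2,

where ``w`` is a scalar weight (an optional per-sample weight vector hook is
provided; at ``w = 1`` WMSE degenerates to MSE).  ``reduction`` is either
the batch mean or the batch maximum of the per-sample terms; for RMSE the
root is applied after the reduction, so the max-reduced RMSE is the largest
absolute residual.

Model comparison uses

    RMSE = sqrt( sum_i (RR_est,i - RR_gt,i)^2 / N )

reported together with the standard deviation of per-sample absolute errors
(the "spread").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor

__all__ = ["LossSpec", "loss", "loss_tensor", "rmse_metric"]

_NAMES = ("mse", "mae", "rmse", "wmse")
_REDUCTIONS = ("mean", "max")


@dataclass(frozen=True)
class LossSpec:
    """Training-loss selection: name, batch reduction, and WMSE weight."""

    name: str = "mse"
    reduction: str = "mean"
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.name.lower() not in _NAMES:
            raise ValueError(f"loss name must be one of {_NAMES}, got {self.name!r}")
        if self.reduction.lower() not in _REDUCTIONS:
            raise ValueError(
                f"reduction must be one of {_REDUCTIONS}, got {self.reduction!r}"
            )
        if self.name.lower() == "wmse" and self.w <= 0:
            raise ValueError(f"wmse weight w must be > 0, got {self.w}")


def _validate(predictions, targets) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: predictions {p.shape} vs targets {t.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    return p, t


def loss(
    spec: LossSpec,
    predictions,
    targets,
    sample_weights=None,
) -> float:
    """Evaluate a loss on arrays (no gradients).

    ``sample_weights`` optionally replaces the scalar WMSE weight with a
    per-sample vector.
    """
    p, t = _validate(predictions, targets)
    name = spec.name.lower()
    red = np.mean if spec.reduction.lower() == "mean" else np.max
    resid = p - t
    if name == "mae":
        return float(red(np.abs(resid)))
    sq = resid**2
    if name == "mse":
        return float(red(sq))
    if name == "rmse":
        return float(np.sqrt(red(sq)))
    w = np.asarray(sample_weights, dtype=float) if sample_weights is not None else spec.w
    return float(red(w * sq))


def loss_tensor(spec: LossSpec, predictions: Tensor, targets: np.ndarray) -> Tensor:
    """Differentiable counterpart of `loss` for training.

    MAE is implemented as sqrt((r^2 + eps)) per sample to stay smooth at
    zero residual; the bias is negligible at bpm scale.
    """
    t = np.asarray(targets, dtype=predictions.data.dtype)
    if predictions.shape != t.shape:
        raise ValueError(f"length mismatch: {predictions.shape} vs {t.shape}")
    resid = predictions - Tensor(t)
    name = spec.name.lower()
    reduce_mean = spec.reduction.lower() == "mean"

    def red(x: Tensor) -> Tensor:
        return x.mean() if reduce_mean else x.max()

    if name == "mae":
        return red(((resid**2) + 1e-12) ** 0.5)
    sq = resid**2
    if name == "mse":
        return red(sq)
    if name == "rmse":
        return (red(sq) + 1e-12) ** 0.5
    return red(sq * spec.w)


def rmse_metric(estimates, ground_truths) -> tuple[float, float]:
    """Root-mean-square error and the spread of absolute errors.

    Returns ``(rmse, spread)`` where ``rmse = sqrt(mean(residual^2))`` and
    ``spread`` is the (population) standard deviation of ``|residual|``.
    """
    est, gt = _validate(estimates, ground_truths)
    resid = est - gt
    rmse = float(np.sqrt(np.mean(resid**2)))
    spread = float(np.std(np.abs(resid)))
    return rmse, spread
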