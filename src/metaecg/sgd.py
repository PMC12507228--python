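"""Plain gradient-descent helpers shared by the training stages."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .backbone import WeightsHandle

__all__ = ["loss_and_grads", "gd_step", "sgd_fit"]


def loss_and_grads(model, weights: WeightsHandle, X, y,
                   training: bool = False, rng=None):
    """One forward/backward pass; returns (loss value, gradient arrays)."""
    params = weights.as_tensors(requires_grad=True)
    loss = model.loss_on(params, X, y, training=training, rng=rng)
    grads = ad.grad(loss, params.values())
    return loss.item(), {k: g.data for k, g in zip(params, grads)}


def gd_step(weights: WeightsHandle, grads: dict, lr: float) -> WeightsHandle:
    return WeightsHandle({k: weights.arrays[k] - lr * grads[k]
                          for k in weights.arrays})


def sgd_fit(model, weights: WeightsHandle, X, y, lr: float, steps: int,
            training: bool = False, rng=None,
            loss_trace: list | None = None) -> WeightsHandle:
    """Full-batch gradient descent for a fixed number of steps."""
    w = weights.copy()
    for _ in range(steps):
        loss, grads = loss_and_grads(model, w, X, y, training=training,
                                     rng=rng)
        if not np.isfinite(loss):
            break
        if loss_trace is not None:
            loss_trace.append(loss)
        w = gd_step(w, grads, lr)
    return w
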