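"""Functional neural-network layers on top of the autodiff core.

All layers are pure functions of explicitly passed parameter tensors, which is
what meta-learning needs: the same architecture can be evaluated under the
meta-weights, under a task-adapted copy, or under any traced function of the
meta-weights, and gradients flow to whichever tensors were supplied.

Parameters live in an ordered ``dict[str, Tensor]``.  Xavier-uniform
initialization is used for weight matrices and convolution kernels.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "xavier_uniform", "linear", "conv1d", "batch_norm", "layer_norm",
    "max_pool1d", "adaptive_avg_pool1d", "dropout",
    "multi_head_attention", "transformer_encoder_layer",
    "cross_entropy_with_logits", "one_hot",
]


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def linear(x, w, b):
    """``x @ w + b`` with ``w`` of shape (in, out)."""
    return ad.matmul(x, w) + b


def conv1d(x, w, b, stride: int = 1, padding: int = 0):
    """1-D convolution (cross-correlation) via an im2col gather.

    x: (N, C_in, L); w: (C_out, C_in, K); b: (C_out,).
    """
    n, c_in, L = x.shape
    c_out, c_in_w, k = w.shape
    if c_in_w != c_in:
        raise ValueError(f"conv1d channel mismatch: input {c_in}, kernel {c_in_w}")
    if padding:
        x = ad.pad_last(x, padding, padding)
    L_pad = L + 2 * padding
    L_out = (L_pad - k) // stride + 1
    if L_out < 1:
        raise ValueError("conv1d: input shorter than kernel")
    idx = np.arange(k)[:, None] + stride * np.arange(L_out)[None, :]
    cols = ad.take_last(x, idx)                      # (N, C_in, K, L_out)
    cols = ad.reshape(cols, (n, c_in * k, L_out))
    wm = ad.reshape(w, (c_out, c_in * k))
    y = ad.matmul(wm, cols)                          # (N, C_out, L_out)
    return y + ad.reshape(b, (1, c_out, 1))


def batch_norm(x, gamma, beta, running_mean, running_var,
               training: bool, momentum: float = 0.1, eps: float = 1e-5):
    """Batch normalization over (N, C, L) per channel.

    In training mode the batch statistics enter the graph (so gradients flow
    through them) and ``running_mean``/``running_var`` numpy buffers are
    updated in place.  In inference mode the running buffers are used as
    constants — this is also the mode used during few-shot inner-loop
    adaptation, where 2K-sample batch statistics would be too noisy.
    """
    c = x.shape[1]
    if training:
        mean = ad.tmean(x, axis=(0, 2), keepdims=True)
        var = ad.tmean((x - mean) ** 2.0, axis=(0, 2), keepdims=True)
        n = x.shape[0] * x.shape[2]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean.data.reshape(c)
        unbiased = var.data.reshape(c) * (n / max(n - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mean = Tensor(running_mean.reshape(1, c, 1))
        var = Tensor(running_var.reshape(1, c, 1))
    xhat = (x - mean) / ad.sqrt(var + eps)
    return xhat * ad.reshape(gamma, (1, c, 1)) + ad.reshape(beta, (1, c, 1))


def layer_norm(x, gamma, beta, eps: float = 1e-5):
    """Layer norm over the last axis (as used inside the transformer layer)."""
    mean = ad.tmean(x, axis=-1, keepdims=True)
    var = ad.tmean((x - mean) ** 2.0, axis=-1, keepdims=True)
    return (x - mean) / ad.sqrt(var + eps) * gamma + beta


def max_pool1d(x, kernel: int = 2):
    n, c, L = x.shape
    L_out = L // kernel
    x = ad.slice_last(x, 0, L_out * kernel)
    x = ad.reshape(x, (n, c, L_out, kernel))
    return ad.tmax_last(x)


def adaptive_avg_pool1d(x, out_len: int):
    """Average pooling to a fixed output length with the standard bin rule
    (bin i spans [floor(i*L/out), ceil((i+1)*L/out))), realized as a matmul
    with a constant pooling matrix."""
    L = x.shape[-1]
    pool = np.zeros((L, out_len))
    for i in range(out_len):
        a = (i * L) // out_len
        b = -(-((i + 1) * L) // out_len)  # ceil
        pool[a:b, i] = 1.0 / (b - a)
    return ad.matmul(x, Tensor(pool))


def dropout(x, p: float, rng: np.random.Generator | None, training: bool):
    if not training or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode requires an rng")
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def _split_heads(x, n_heads: int):
    n, t, d = x.shape
    dk = d // n_heads
    x = ad.reshape(x, (n, t, n_heads, dk))
    return ad.transpose(x, (0, 2, 1, 3))            # (N, h, T, dk)


def _merge_heads(x):
    n, h, t, dk = x.shape
    x = ad.transpose(x, (0, 2, 1, 3))
    return ad.reshape(x, (n, t, h * dk))


def multi_head_attention(x, p: Mapping, prefix: str, n_heads: int):
    """Self-attention; parameter names ``{prefix}.wq/wk/wv/wo`` + biases."""
    d = x.shape[-1]
    dk = d // n_heads
    q = _split_heads(linear(x, p[f"{prefix}.wq"], p[f"{prefix}.bq"]), n_heads)
    k = _split_heads(linear(x, p[f"{prefix}.wk"], p[f"{prefix}.bk"]), n_heads)
    v = _split_heads(linear(x, p[f"{prefix}.wv"], p[f"{prefix}.bv"]), n_heads)
    scores = ad.matmul(q, ad.transpose_last2(k)) * (1.0 / np.sqrt(dk))
    attn = ad.softmax_last(scores)
    out = _merge_heads(ad.matmul(attn, v))
    return linear(out, p[f"{prefix}.wo"], p[f"{prefix}.bo"])


def transformer_encoder_layer(x, p: Mapping, prefix: str, n_heads: int):
    """Post-norm encoder layer: self-attention and a ReLU feed-forward block,
    each wrapped in a residual connection followed by layer norm."""
    a = multi_head_attention(x, p, prefix, n_heads)
    x = layer_norm(x + a, p[f"{prefix}.ln1_g"], p[f"{prefix}.ln1_b"])
    h = ad.relu(linear(x, p[f"{prefix}.w1"], p[f"{prefix}.b1"]))
    f = linear(h, p[f"{prefix}.w2"], p[f"{prefix}.b2"])
    return layer_norm(x + f, p[f"{prefix}.ln2_g"], p[f"{prefix}.ln2_b"])


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    eye = np.eye(n_classes)
    return eye[labels]


def cross_entropy_with_logits(logits, labels: np.ndarray):
    """Mean cross-entropy of 2-logit (or n-logit) outputs against int labels."""
    n_classes = logits.shape[-1]
    oh = Tensor(one_hot(labels, n_classes))
    logp = logits - ad.logsumexp_last(logits)
    return -ad.tmean(ad.tsum(logp * oh, axis=-1))
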