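"""Classifier backbones behind a model-agnostic interface.

The meta-learning and personalization stages only ever touch a backbone
through three things: an initial :class:`WeightsHandle`, ``forward(params,
x)`` and ``loss_on(params, X, y)``.  Any object with that surface can be
meta-trained, which is the point — the default network below is one choice,
not a dependency of the method.

The default backbone is a lightweight 1-D convolution + transformer network
for 2-s, 200-Hz ECG windows (400 samples):

* two parallel convolutions (kernel 5 and 9, stride 2) fused by element-wise
  averaging, then batch-norm → ReLU → max-pool(2) → dropout(0.5);
* a convolution block (kernel 8) with batch-norm → ReLU → adaptive average
  pooling to 50 positions at 64 channels;
* one transformer encoder layer (width 64, 8 heads);
* mean over the 50 positions and a linear map to 2 logits.
"""

from __future__ import annotations

import copy
import json
from collections import OrderedDict
from dataclasses import dataclass, asdict, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = [
    "BackboneConfig", "WeightsHandle", "ConvTransformerBackbone",
    "MLPBackbone", "build_backbone", "count_params",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class BackboneConfig:
    in_len: int = 400
    conv_channels: int = 128
    kernel_a: int = 5
    kernel_b: int = 9
    conv_stride: int = 2
    dropout: float = 0.5
    block_channels: int = 64
    block_kernel: int = 8
    pooled_len: int = 50
    attn_dim: int = 64
    attn_heads: int = 8
    ffn_dim: int = 2048
    n_classes: int = 2

    def validate(self):
        if self.attn_dim % self.attn_heads != 0:
            raise ValueError("attn_dim must be divisible by attn_heads")
        if self.pooled_len < 1:
            raise ValueError("pooled_len must be >= 1")
        if self.block_channels != self.attn_dim:
            raise ValueError("block_channels must equal attn_dim "
                             "(the conv block feeds the encoder directly)")


class WeightsHandle:
    """An ordered, copyable snapshot of named parameter arrays.

    Plays every role a weight vector takes in the training pipeline: the
    meta-weights, a per-task adapted copy, and the intermediate snapshots of
    pre-fine-tuning.  Deep copies are fully independent.
    """

    def __init__(self, arrays: OrderedDict[str, np.ndarray]):
        self.arrays = OrderedDict(
            (k, np.asarray(v, dtype=np.float64)) for k, v in arrays.items())

    def copy(self) -> "WeightsHandle":
        return WeightsHandle(OrderedDict(
            (k, v.copy()) for k, v in self.arrays.items()))

    __deepcopy__ = lambda self, memo: self.copy()

    def as_tensors(self, requires_grad: bool = True) -> OrderedDict[str, Tensor]:
        return OrderedDict(
            (k, Tensor(v.copy(), requires_grad=requires_grad))
            for k, v in self.arrays.items())

    @staticmethod
    def from_tensors(tensors) -> "WeightsHandle":
        return WeightsHandle(OrderedDict(
            (k, t.data.copy()) for k, t in tensors.items()))

    def allclose(self, other: "WeightsHandle", rtol=1e-12, atol=1e-12) -> bool:
        return (self.arrays.keys() == other.arrays.keys()
                and all(np.allclose(self.arrays[k], other.arrays[k],
                                    rtol=rtol, atol=atol)
                        for k in self.arrays))

    def n_params(self) -> int:
        return sum(v.size for v in self.arrays.values())

    def keys(self):
        return self.arrays.keys()

    def __getitem__(self, k):
        return self.arrays[k]


def _params_dict(params) -> OrderedDict[str, Tensor]:
    if isinstance(params, WeightsHandle):
        return params.as_tensors(requires_grad=False)
    return params


class ConvTransformerBackbone:
    """The default convolution + attention network (see module docstring)."""

    def __init__(self, config: BackboneConfig | None = None):
        self.config = config or BackboneConfig()
        self.config.validate()
        c = self.config
        self.bn1_mean = np.zeros(c.conv_channels)
        self.bn1_var = np.ones(c.conv_channels)
        self.bn2_mean = np.zeros(c.block_channels)
        self.bn2_var = np.ones(c.block_channels)

    # -- init ----------------------------------------------------------
    def init_params(self, seed: int) -> WeightsHandle:
        c = self.config
        rng = np.random.default_rng(seed)
        p: OrderedDict[str, np.ndarray] = OrderedDict()

        def conv_w(name, c_out, c_in, k):
            p[f"{name}.w"] = nn.xavier_uniform(
                rng, (c_out, c_in, k), fan_in=c_in * k, fan_out=c_out * k)
            p[f"{name}.b"] = np.zeros(c_out)

        def lin_w(name, d_in, d_out):
            p[f"{name}.w"] = nn.xavier_uniform(
                rng, (d_in, d_out), fan_in=d_in, fan_out=d_out)
            p[f"{name}.b"] = np.zeros(d_out)

        conv_w("conv1", c.conv_channels, 1, c.kernel_a)
        conv_w("conv2", c.conv_channels, 1, c.kernel_b)
        p["bn1.g"] = np.ones(c.conv_channels)
        p["bn1.b"] = np.zeros(c.conv_channels)
        conv_w("block", c.block_channels, c.conv_channels, c.block_kernel)
        p["bn2.g"] = np.ones(c.block_channels)
        p["bn2.b"] = np.zeros(c.block_channels)
        d = c.attn_dim
        for nm in ("wq", "wk", "wv", "wo"):
            p[f"enc.{nm}"] = nn.xavier_uniform(rng, (d, d), d, d)
            p[f"enc.b{nm[1]}"] = np.zeros(d)
        p["enc.ln1_g"] = np.ones(d)
        p["enc.ln1_b"] = np.zeros(d)
        lin_w("enc.ff1", d, c.ffn_dim)
        lin_w("enc.ff2", c.ffn_dim, d)
        p["enc.ln2_g"] = np.ones(d)
        p["enc.ln2_b"] = np.zeros(d)
        lin_w("fc", d, c.n_classes)
        return WeightsHandle(p)

    # -- forward ---------------------------------------------------------
    def forward(self, params, x, training: bool = False, rng=None) -> Tensor:
        """Logits for a batch of windows.

        ``x``: (N, in_len) or (N, 1, in_len).  ``training=True`` enables
        batch-statistics batch-norm (updating the running buffers) and
        dropout; inference/adaptation mode is fully deterministic and uses
        the frozen running statistics.
        """
        p = _params_dict(params)
        c = self.config
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[-1] != c.in_len:
            raise ValueError(f"expected windows of {c.in_len} samples, "
                             f"got {x.shape[-1]}")
        x = Tensor(x)

        a = nn.conv1d(x, p["conv1.w"], p["conv1.b"],
                      stride=c.conv_stride, padding=c.kernel_a // 2)
        b = nn.conv1d(x, p["conv2.w"], p["conv2.b"],
                      stride=c.conv_stride, padding=c.kernel_b // 2)
        h = (a + b) * 0.5                     # feature fusion by averaging
        h = nn.batch_norm(h, p["bn1.g"], p["bn1.b"],
                          self.bn1_mean, self.bn1_var, training)
        h = ad.relu(h)
        h = nn.max_pool1d(h, 2)
        h = nn.dropout(h, c.dropout, rng, training)
        h = nn.conv1d(h, p["block.w"], p["block.b"],
                      stride=1, padding=c.block_kernel // 2)
        h = nn.batch_norm(h, p["bn2.g"], p["bn2.b"],
                          self.bn2_mean, self.bn2_var, training)
        h = ad.relu(h)
        h = nn.adaptive_avg_pool1d(h, c.pooled_len)
        h = ad.transpose(h, (0, 2, 1))        # (N, pooled_len, attn_dim)
        # encoder params under names nn.transformer_encoder_layer expects
        enc = {f"enc.{k}": p[f"enc.{k}"] for k in
               ("wq", "bq", "wk", "bk", "wv", "bv", "wo", "bo",
                "ln1_g", "ln1_b", "ln2_g", "ln2_b")}
        enc["enc.w1"], enc["enc.b1"] = p["enc.ff1.w"], p["enc.ff1.b"]
        enc["enc.w2"], enc["enc.b2"] = p["enc.ff2.w"], p["enc.ff2.b"]
        h = nn.transformer_encoder_layer(h, enc, "enc", c.attn_heads)
        h = ad.tmean(h, axis=1)               # global average pooling
        return nn.linear(h, p["fc.w"], p["fc.b"])

    def loss_on(self, params, X, y, training: bool = False, rng=None,
                reduction: str = "mean") -> Tensor:
        logits = self.forward(params, X, training=training, rng=rng)
        loss = nn.cross_entropy_with_logits(logits, y)
        if reduction == "sum":
            loss = loss * float(len(np.asarray(y)))
        return loss


class MLPBackbone:
    """A small multilayer perceptron over raw window samples.

    Exists to demonstrate (and test) that the meta-learning pipeline is
    backbone-agnostic, and serves as the desk-scale default where the full
    convolution + attention network would be needlessly slow.
    """

    def __init__(self, in_len: int = 400, hidden: tuple[int, ...] = (32,),
                 n_classes: int = 2, dropout: float = 0.5):
        self.config = {"kind": "mlp", "in_len": in_len,
                       "hidden": list(hidden), "n_classes": n_classes,
                       "dropout": dropout}
        self.in_len = in_len
        self.dropout = dropout
        self.dims = [in_len, *hidden, n_classes]

    def init_params(self, seed: int) -> WeightsHandle:
        rng = np.random.default_rng(seed)
        p = OrderedDict()
        for i, (d_in, d_out) in enumerate(zip(self.dims[:-1], self.dims[1:])):
            p[f"l{i}.w"] = nn.xavier_uniform(rng, (d_in, d_out), d_in, d_out)
            p[f"l{i}.b"] = np.zeros(d_out)
        return WeightsHandle(p)

    def forward(self, params, x, training: bool = False, rng=None) -> Tensor:
        p = _params_dict(params)
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, 0, :]
        h = Tensor(x)
        n_layers = len(self.dims) - 1
        for i in range(n_layers):
            h = nn.linear(h, p[f"l{i}.w"], p[f"l{i}.b"])
            if i < n_layers - 1:
                h = ad.relu(h)
                h = nn.dropout(h, self.dropout, rng, training)
        return h

    def loss_on(self, params, X, y, training: bool = False, rng=None,
                reduction: str = "mean") -> Tensor:
        logits = self.forward(params, X, training=training, rng=rng)
        loss = nn.cross_entropy_with_logits(logits, y)
        if reduction == "sum":
            loss = loss * float(len(np.asarray(y)))
        return loss


def build_backbone(config: BackboneConfig | None = None, seed: int = 0):
    """Construct the default backbone and its Xavier-initialized weights."""
    model = ConvTransformerBackbone(config)
    return model, model.init_params(seed)


def count_params(weights: WeightsHandle) -> int:
    """Exact count of trainable scalars in a weights handle."""
    return weights.n_params()


# ---------------------------------------------------------------------------
# checkpoints: named-tensor .npz archive + JSON header
# ---------------------------------------------------------------------------

def save_checkpoint(path, weights: WeightsHandle, config=None, seed=None,
                    stage: str = "pretrained"):
    header = {"config": asdict(config) if hasattr(config, "__dataclass_fields__")
              else config, "seed": seed, "stage": stage,
              "names": list(weights.keys())}
    arrays = dict(weights.arrays)
    arrays["__header__"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"].tobytes()).decode("utf-8"))
        arrays = OrderedDict((k, z[k]) for k in header["names"])
    return WeightsHandle(arrays), header
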