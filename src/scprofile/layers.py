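"""Neural-network building blocks on top of :mod:`scprofile.minigrad`.

Provides the module system (parameter registration, train/eval mode,
state dicts), the layers used by the sequence backbone and hypernetwork
decoder (linear, strided 1-D convolution, batch/layer norm, dropout,
self-attention), and low-rank adaptation (LoRA) of linear and
convolutional layers: additive trainable factors ``B @ A`` on frozen base
weights, mergeable back into the weights after training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .minigrad import Tensor

__all__ = [
    "Module", "Parameter", "Linear", "Conv1d", "BatchNorm1d", "ChannelNorm",
    "LayerNorm",
    "Dropout", "SelfAttention", "TransformerBlock", "LoRAConfig",
    "inject_lora", "merge_lora", "adapter_parameters",
]

# layer kinds that LoRA can target
KIND_CONV = "convolution"
KIND_ATTN_Q = "attention-query"
KIND_ATTN_V = "attention-value"
KIND_MLP = "mlp-projection"
ALL_KINDS = (KIND_CONV, KIND_ATTN_Q, KIND_ATTN_V, KIND_MLP)


class Parameter(Tensor):
    def __init__(self, data, name=None):
        super().__init__(data, requires_grad=True, name=name)


class Module:
    """Base class; child modules and parameters are found by attribute walk."""

    def __init__(self):
        self.training = True

    # -- registration-free discovery -----------------------------------------
    def named_parameters(self, prefix: str = ""):
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, Parameter):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialization ----------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm1d):
                state[f"__buffers__.{i}.running_mean"] = m.running_mean.copy()
                state[f"__buffers__.{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.array(state[name], dtype=np.float64)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm1d):
                m.running_mean = np.array(state[f"__buffers__.{i}.running_mean"])
                m.running_var = np.array(state[f"__buffers__.{i}.running_var"])
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _init_weight(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    scale = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-scale, scale, size=shape)


class _Adaptable(Module):
    """Mixin for layers supporting a LoRA adapter on their weight matrix.

    The weight is viewed as a matrix of shape (fan_out, fan_in_flat); the
    adapter contributes ``scaling * (B @ A)`` reshaped to the weight shape,
    with A of shape (rank, fan_in_flat) and B of shape (fan_out, rank).
    B is zero-initialized so injection leaves the forward pass unchanged.
    """

    weight: Parameter
    lora_A: Parameter | None
    lora_B: Parameter | None
    lora_scaling: float

    def _init_adapter(self):
        self.lora_A = None
        self.lora_B = None
        self.lora_scaling = 0.0
        self.kind = None

    @property
    def has_adapter(self) -> bool:
        return self.lora_A is not None

    def _weight_matrix_shape(self) -> tuple[int, int]:
        w = self.weight.data
        return w.shape[0], int(np.prod(w.shape[1:]))

    def add_adapter(self, rank: int, alpha: float, rng: np.random.Generator):
        fan_out, fan_in = self._weight_matrix_shape()
        if rank < 1 or rank > min(fan_out, fan_in):
            raise ValueError(
                f"LoRA rank {rank} invalid for layer of shape "
                f"({fan_out}, {fan_in})"
            )
        self.lora_A = Parameter(rng.normal(0.0, 0.02, size=(rank, fan_in)))
        self.lora_B = Parameter(np.zeros((fan_out, rank)))
        self.lora_scaling = float(alpha) / float(rank)
        self.weight.requires_grad = False
        if getattr(self, "bias", None) is not None:
            self.bias.requires_grad = False

    def remove_adapter(self, merge: bool):
        if merge:
            delta = self.lora_scaling * (self.lora_B.data @ self.lora_A.data)
            self.weight.data = self.weight.data + delta.reshape(self.weight.data.shape)
        self.lora_A = None
        self.lora_B = None
        self.lora_scaling = 0.0
        self.weight.requires_grad = True
        if getattr(self, "bias", None) is not None:
            self.bias.requires_grad = True

    def effective_weight(self) -> Tensor:
        if not self.has_adapter:
            return self.weight
        delta = (self.lora_B @ self.lora_A) * self.lora_scaling
        return self.weight + delta.reshape(self.weight.data.shape)


class Linear(_Adaptable):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True,
                 kind: str | None = None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_init_weight(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None
        self._init_adapter()
        self.kind = kind

    def forward(self, x: Tensor) -> Tensor:
        w = self.effective_weight()
        y = x @ w.transpose()
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv1d(_Adaptable):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True, kind: str | None = KIND_CONV):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size
        self.weight = Parameter(
            _init_weight(rng, (out_channels, in_channels, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._init_adapter()
        self.kind = kind

    def forward(self, x: Tensor) -> Tensor:
        w = self.effective_weight()
        return x.conv1d(w, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm1d(Module):
    """Channel-wise batch norm for (B, C, L) inputs with running statistics.

    ``freeze()`` pins the layer to its running statistics (no batch stats,
    no updates) regardless of training mode — the first-training-step
    stabilization protocol hooks into this.
    """

    def __init__(self, num_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))
        self.running_mean = np.zeros(num_channels)
        self.running_var = np.ones(num_channels)
        self.momentum = momentum
        self.eps = eps
        self.frozen = False

    def freeze(self):
        self.frozen = True

    def unfreeze(self):
        self.frozen = False

    def forward(self, x: Tensor) -> Tensor:
        if self.training and not self.frozen:
            mu = x.mean(axis=(0, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xn = xc * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1)
            xn = (x - mu) * (1.0 / sd)
        return xn * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class ChannelNorm(Module):
    """Position-wise normalization over channels for (B, C, L) inputs.

    Batch-independent (training and inference behave identically), so
    per-window activation scales are preserved across modes — the property
    batch norm lacks at small batch sizes.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class LayerNorm(Module):
    """Normalization over the last axis (used inside transformer blocks)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng
        self.enabled = True

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or not self.enabled or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = self.rng.random(x.shape) < keep
        return x * (mask.astype(np.float64) / keep)


class SelfAttention(Module):
    """Single-head scaled dot-product self-attention over (B, L, C).

    Only the query and value projections are LoRA-adaptable, mirroring the
    fine-tuning recipe (query, value and MLP projections; keys untouched).
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.dim = dim
        self.q = Linear(dim, dim, rng, kind=KIND_ATTN_Q)
        self.k = Linear(dim, dim, rng, kind=None)
        self.v = Linear(dim, dim, rng, kind=KIND_ATTN_V)
        self.out = Linear(dim, dim, rng, kind=None)

    def forward(self, x: Tensor) -> Tensor:
        q, k, v = self.q(x), self.k(x), self.v(x)
        scores = (q @ k.transpose((0, 2, 1))) * (1.0 / np.sqrt(self.dim))
        attn = scores.softmax(axis=-1)
        return self.out(attn @ v)


class TransformerBlock(Module):
    def __init__(self, dim: int, mlp_ratio: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = SelfAttention(dim, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp_in = Linear(dim, dim * mlp_ratio, rng, kind=KIND_MLP)
        self.mlp_out = Linear(dim * mlp_ratio, dim, rng, kind=KIND_MLP)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        h = self.mlp_out(self.drop(self.mlp_in(self.norm2(x)).gelu()))
        return x + h


@dataclass
class LoRAConfig:
    """Low-rank adaptation settings.

    rank: adapter rank (the fine-tuning recipe uses 8).
    alpha: scaling numerator; the additive term is (alpha/rank) * B @ A.
        Defaults to rank (scaling 1).
    target_kinds: which layer kinds receive adapters.
    """

    rank: int = 8
    alpha: float | None = None
    target_kinds: tuple = field(default=ALL_KINDS)

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("LoRA rank must be >= 1")
        if self.alpha is None:
            self.alpha = float(self.rank)


def inject_lora(backbone: Module, config: LoRAConfig, seed: int = 0) -> Module:
    """Add zero-initialized LoRA adapters to all targeted layers in place.

    Base weights (including biases of every layer of the backbone) are
    flagged frozen; adapter parameters are enumerable via
    ``adapter_parameters``. Because B is zero-initialized the forward pass
    is unchanged immediately after injection.
    """
    rng = np.random.default_rng(seed)
    for p in backbone.parameters():
        p.requires_grad = False
    n = 0
    for m in backbone.modules():
        if isinstance(m, _Adaptable) and m.kind in config.target_kinds:
            m.add_adapter(config.rank, config.alpha, rng)
            n += 1
    if n == 0:
        warnings.warn("inject_lora: no layer matched the targeted kinds")
    return backbone


def merge_lora(backbone: Module, warn_if_absent: bool = True) -> Module:
    """Fold every adapter into its base weight and remove the adapters.

    After merging, the backbone has its original parameter count and its
    forward pass matches the adapted forward up to floating-point error.
    """
    merged = 0
    for m in backbone.modules():
        if isinstance(m, _Adaptable) and m.has_adapter:
            m.remove_adapter(merge=True)
            merged += 1
    if merged == 0 and warn_if_absent:
        warnings.warn("merge_lora: backbone has no adapters; no-op")
    for p in backbone.parameters():
        p.requires_grad = True
    return backbone


def adapter_parameters(backbone: Module):
    """Yield (name, parameter) for every LoRA factor in the backbone."""
    for name, p in backbone.named_parameters():
        if name.endswith("lora_A") or name.endswith("lora_B"):
            yield name, p
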