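"""Neural-network building blocks for the multi-stream residual classifier.

Contains the generic layers (Linear, Conv2d, BatchNorm, Dropout), the
squeeze-and-excitation channel-attention module, channel shuffle, and the
Re-SE residual unit (a residual block whose branch output is SE-recalibrated
before the identity addition). Array-level functional forms of the
primitives (``se_squeeze``, ``se_excite``, ``channel_shuffle_array``,
``grouped_pointwise_conv``) are exposed for direct use and testing.
"""

from __future__ import annotations

import math

import numpy as np

from ..exceptions import DimensionError
from .autograd import Parameter, Tensor, conv2d

__all__ = [
    "Module", "Linear", "Conv2d", "BatchNorm", "Dropout",
    "SqueezeExcitation", "ReSEBlock", "Adam",
    "se_squeeze", "se_excite", "channel_shuffle", "channel_shuffle_array",
    "grouped_pointwise_conv", "se_hidden_width", "se_param_count",
]


# ---------------------------------------------------------------------------
# module infrastructure

class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def _children(self):
        for val in vars(self).values():
            if isinstance(val, Module):
                yield val
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield item

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            d[name] = buf.copy()
        return d

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if name in ("running_mean", "running_var") and isinstance(val, np.ndarray):
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_buffers(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_buffers(prefix=f"{key}.{i}."))
        return out

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in d.items():
            if name in params:
                params[name].data = np.array(arr, dtype=np.float64)
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unknown parameter {name!r}")


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(_kaiming_uniform(rng, (in_features, out_features),
                                                 in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y

    __call__ = forward


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 rng: np.random.Generator, stride=(1, 1), padding=(0, 0),
                 groups: int = 1, bias: bool = True):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        if in_channels % groups or out_channels % groups:
            raise DimensionError(
                f"channels ({in_channels}->{out_channels}) must be divisible by groups={groups}")
        self.stride = (stride, stride) if isinstance(stride, int) else stride
        self.padding = (padding, padding) if isinstance(padding, int) else padding
        self.groups = groups
        fan_in = (in_channels // groups) * kh * kw
        self.weight = Parameter(_kaiming_uniform(
            rng, (out_channels, in_channels // groups, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding, groups=self.groups)

    __call__ = forward


class BatchNorm(Module):
    """Batch normalization over the channel axis for [B,C] or [B,C,H,W] input."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 zero_init_scale: bool = False):
        super().__init__()
        self.num_features = num_features
        self.momentum, self.eps = momentum, eps
        init = 0.0 if zero_init_scale else 1.0
        self.gamma = Parameter(np.full(num_features, init, dtype=np.float64))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) if x.ndim == 2 else (0, 2, 3)
        shape = (1, self.num_features) + (1,) * (x.ndim - 2)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)

    __call__ = forward


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {p}")
        self.p, self.rng = p, rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)

    __call__ = forward


# ---------------------------------------------------------------------------
# squeeze-and-excitation

def se_squeeze(feature_map: np.ndarray) -> np.ndarray:
    """Global average pooling: [N,H,W] (or [B,N,H,W]) -> per-channel means."""
    x = np.asarray(feature_map, dtype=np.float64)
    if x.ndim not in (3, 4):
        raise DimensionError(f"expected [N,H,W] or [B,N,H,W], got shape {x.shape}")
    return x.mean(axis=(-2, -1))


def se_hidden_width(n_channels: int, ratio: int) -> int:
    """Bottleneck width of the excitation MLP: ceil(N/k), at least 1."""
    return max(1, -(-n_channels // ratio))


def se_param_count(n_channels: int, ratio: int, bias: bool = True) -> int:
    h = se_hidden_width(n_channels, ratio)
    n = n_channels * h + h * n_channels
    if bias:
        n += h + n_channels
    return n


def se_excite(z: np.ndarray, w1: np.ndarray, b1: np.ndarray,
              w2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Two-FC excitation: gates = sigmoid(w2 @ relu(w1 @ z + b1) + b2).

    z: [N] or [B,N]; w1: [N,h]; w2: [h,N]. Gates lie strictly in (0,1).
    """
    z = np.asarray(z, dtype=np.float64)
    if z.shape[-1] != w1.shape[0] or w1.shape[1] != w2.shape[0] or w2.shape[1] != z.shape[-1]:
        raise DimensionError(
            f"excitation weight shapes {w1.shape}/{w2.shape} do not match {z.shape[-1]} channels")
    h = np.maximum(z @ w1 + b1, 0.0)
    return 1.0 / (1.0 + np.exp(-(h @ w2 + b2)))


class SqueezeExcitation(Module):
    """Channel attention: GAP -> FC (compress by ratio) -> ReLU -> FC -> sigmoid."""

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator):
        super().__init__()
        hidden = se_hidden_width(channels, ratio)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def gates(self, x: Tensor) -> Tensor:
        z = x.mean(axis=(2, 3))                       # squeeze
        return self.fc2(self.fc1(z).relu()).sigmoid()  # excite

    def forward(self, x: Tensor) -> Tensor:
        s = self.gates(x)
        B, C = s.shape
        return x * s.reshape(B, C, 1, 1)

    __call__ = forward


# ---------------------------------------------------------------------------
# channel shuffle and grouped pointwise convolution

def channel_shuffle_array(x: np.ndarray, groups: int, axis: int = 0) -> np.ndarray:
    """Permute channels by reshape (g, N/g) -> transpose -> flatten."""
    x = np.asarray(x)
    n = x.shape[axis]
    if n % groups:
        raise DimensionError(f"{n} channels not divisible by {groups} groups")
    shape = x.shape[:axis] + (groups, n // groups) + x.shape[axis + 1:]
    y = x.reshape(shape)
    y = np.swapaxes(y, axis, axis + 1)
    return y.reshape(x.shape).copy()


def channel_shuffle(x: Tensor, groups: int, axis: int = 1) -> Tensor:
    """Channel shuffle on a Tensor (default axis=1: [B,C,H,W] layout)."""
    n = x.shape[axis]
    if n % groups:
        raise DimensionError(f"{n} channels not divisible by {groups} groups")
    shape = x.shape[:axis] + (groups, n // groups) + x.shape[axis + 1:]
    perm = list(range(len(shape)))
    perm[axis], perm[axis + 1] = perm[axis + 1], perm[axis]
    return x.reshape(shape).transpose(tuple(perm)).reshape(x.shape)


def grouped_pointwise_conv(x: np.ndarray, groups: int, weights: np.ndarray,
                           bias: np.ndarray | None = None) -> np.ndarray:
    """1x1 convolution within channel groups on a [N_in,H,W] array.

    weights: [N_out, N_in/groups]. Parameter count is N_in*N_out/groups,
    i.e. 1/groups of a dense pointwise convolution.
    """
    x = np.asarray(x, dtype=np.float64)
    n_out, n_in_g = weights.shape
    n_in = x.shape[0]
    if n_in % groups or n_out % groups:
        raise DimensionError(
            f"channels ({n_in}->{n_out}) must be divisible by groups={groups}")
    if n_in_g != n_in // groups:
        raise DimensionError(
            f"weights expect {n_in_g} in-channels per group, got {n_in // groups}")
    xg = x.reshape(groups, n_in // groups, *x.shape[1:])
    wg = weights.reshape(groups, n_out // groups, n_in_g)
    y = np.einsum("goi,gihw->gohw", wg, xg).reshape(n_out, *x.shape[1:])
    if bias is not None:
        y += np.asarray(bias).reshape(n_out, *([1] * (x.ndim - 1)))
    return y


# ---------------------------------------------------------------------------
# Re-SE residual unit

class ReSEBlock(Module):
    """Residual unit with SE recalibration: y = shortcut(x) + SE(F(x)).

    F = grouped 1x1 conv -> channel shuffle -> 3x3 conv -> BN -> ReLU
        -> grouped 1x1 conv -> BN(zero-init scale).
    The shortcut is identity when shapes match, else a strided 1x1 projection.
    The last BN scale starts at zero so the block is an identity map at
    initialization, which keeps early gradients well conditioned.
    """

    def __init__(self, in_channels: int, out_channels: int, groups: int,
                 se_ratio: int, rng: np.random.Generator, stride=(1, 1)):
        super().__init__()
        self.groups = groups
        g = groups if in_channels % groups == 0 and out_channels % groups == 0 else 1
        self.conv1 = Conv2d(in_channels, out_channels, 1, rng, groups=g, bias=False)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng, stride=stride,
                            padding=1, groups=1, bias=False)
        self.bn2 = BatchNorm(out_channels)
        g2 = groups if out_channels % groups == 0 else 1
        self.conv3 = Conv2d(out_channels, out_channels, 1, rng, groups=g2, bias=False)
        self.bn3 = BatchNorm(out_channels, zero_init_scale=True)
        self.se = SqueezeExcitation(out_channels, se_ratio, rng)
        self._shuffle_groups = g
        if in_channels != out_channels or stride != (1, 1):
            self.shortcut = Conv2d(in_channels, out_channels, 1, rng,
                                   stride=stride, bias=False)
        else:
            self.shortcut = None

    def branch(self, x: Tensor) -> Tensor:
        h = self.conv1(x)
        h = channel_shuffle(h, self._shuffle_groups)
        h = self.bn2(self.conv2(h)).relu()
        return self.bn3(self.conv3(h))

    def forward(self, x: Tensor) -> Tensor:
        identity = x if self.shortcut is None else self.shortcut(x)
        return identity + self.se(self.branch(x))

    __call__ = forward


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam with optional cosine learning-rate decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 cosine_decay_steps: int | None = None):
        self.params = list(params)
        self.lr0 = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.cosine_decay_steps = cosine_decay_steps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    @property
    def lr(self) -> float:
        if not self.cosine_decay_steps:
            return self.lr0
        frac = min(self.t / self.cosine_decay_steps, 1.0)
        return self.lr0 * 0.5 * (1.0 + math.cos(math.pi * frac))

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        lr = self.lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
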