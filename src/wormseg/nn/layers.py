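"""Neural-network building blocks on top of :mod:`wormseg.nn.tensor`.

Initialisation is explicit: every layer takes a ``numpy.random.Generator`` so
that model construction is a pure function of the seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concatenate

__all__ = [
    "Module", "Parameter", "Linear", "Conv2d", "ConvTranspose2d",
    "GroupNorm", "LayerNorm", "MultiHeadSelfAttention", "AttentionPool",
    "Sequential", "ReLU", "GELU", "Identity", "concatenate",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery (pytorch-style)."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params, seen):
        for v in self.__dict__.values():
            if isinstance(v, Parameter) and id(v) not in seen:
                seen.add(id(v))
                params.append(v)
            elif isinstance(v, Module):
                v._collect(params, seen)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item._collect(params, seen)
                    elif isinstance(item, Parameter) and id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        self._state("", out)
        return out

    def _state(self, prefix, out):
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                out[prefix + k] = v.data.copy()
            elif isinstance(v, Module):
                v._state(f"{prefix}{k}.", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._state(f"{prefix}{k}.{i}.", out)
                    elif isinstance(item, Parameter):
                        out[f"{prefix}{k}.{i}"] = item.data.copy()

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = {}
        self._named("", own)
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=p.data.dtype).copy()

    def _named(self, prefix, out):
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                out[prefix + k] = v
            elif isinstance(v, Module):
                v._named(f"{prefix}{k}.", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._named(f"{prefix}{k}.{i}.", out)
                    elif isinstance(item, Parameter):
                        out[f"{prefix}{k}.{i}"] = item

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Parameter(_kaiming(rng, (d_in, d_out), d_in))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (c_out, c_in, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (c_in, c_out, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, self.stride,
                                  self.padding)


class GroupNorm(Module):
    """Group normalisation over (C/G, H, W) groups; batch-size independent."""

    def __init__(self, n_groups: int, n_channels: int, eps: float = 1e-5):
        if n_channels % n_groups:
            raise ValueError("n_channels must be divisible by n_groups")
        self.n_groups = n_groups
        self.eps = eps
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        g = self.n_groups
        xg = x.reshape(b, g, c // g * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xn = (xg - mu) * ((var + self.eps) ** -0.5)
        xn = xn.reshape(b, c, h, w)
        return xn * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    # (B, S, D) -> (B, H, S, D/H)
    b, s, d = x.shape
    return x.reshape(b, s, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, s, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, s, h * dh)


def _attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    dh = q.shape[-1]
    scores = (q @ k.transpose(0, 1, 3, 2)) * (dh**-0.5)
    return scores.softmax(axis=-1) @ v


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"token dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        q = _split_heads(self.wq(x), self.n_heads)
        k = _split_heads(self.wk(x), self.n_heads)
        v = _split_heads(self.wv(x), self.n_heads)
        return self.wo(_merge_heads(_attention(q, k, v)))


class AttentionPool(Module):
    """Pooling by multi-head attention with a single learnable seed vector.

    The seed query cross-attends over the full token sequence, so the pooled
    representation is a convex combination of (projected) tokens and is
    invariant to duplicating the sequence.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"token dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.seed = Parameter(rng.normal(0.0, 1.0 / np.sqrt(dim), size=(1, 1, dim)))
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def forward(self, tokens: Tensor) -> Tensor:
        b = tokens.shape[0]
        seed = concatenate([self.seed] * b, axis=0) if b > 1 else self.seed
        q = _split_heads(self.wq(seed), self.n_heads)
        k = _split_heads(self.wk(tokens), self.n_heads)
        v = _split_heads(self.wv(tokens), self.n_heads)
        pooled = self.wo(_merge_heads(_attention(q, k, v)))  # (B, 1, D)
        return pooled.reshape(b, pooled.shape[-1])
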