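"""Neural-network building blocks on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["Module", "Linear", "MLP", "LayerNorm", "sinusoidal_embedding"]


class Module:
    """Base class: recursive parameter collection and state (de)serialization."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data[...] = arr


def _collect(v):
    if isinstance(v, Tensor) and v.requires_grad:
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)
    elif isinstance(v, dict):
        for item in v.values():
            yield from _collect(item)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            scale = np.sqrt(2.0 / (d_in + d_out))
            w = rng.normal(0.0, scale, size=(d_in, d_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class MLP(Module):
    def __init__(self, dims: list[int], rng: np.random.Generator,
                 activation: str = "relu", zero_init_last: bool = False):
        self.layers = [
            Linear(a, b, rng, zero_init=(zero_init_last and i == len(dims) - 2))
            for i, (a, b) in enumerate(zip(dims[:-1], dims[1:]))
        ]
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu() if self.activation == "relu" else x.tanh()
        return x


class LayerNorm(Module):
    """Normalization over the last axis with learnable affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * (var + self.eps).pow(-0.5)
        return xn * self.gamma + self.beta

    def normalize_only(self, x: Tensor) -> Tensor:
        """Instance normalization without the affine (used by AdaIN)."""
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps).pow(-0.5)


def sinusoidal_embedding(t: float, dim: int, max_period: float = 10_000.0) -> np.ndarray:
    """Standard transformer timestep embedding for a scalar t."""
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / max(half - 1, 1))
    ang = t * freqs
    emb = np.concatenate([np.sin(ang), np.cos(ang)])
    if emb.size < dim:
        emb = np.concatenate([emb, np.zeros(dim - emb.size)])
    return emb
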