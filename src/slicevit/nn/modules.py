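"""Layer primitives built on the autodiff tensor."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Parameter, Tensor

__all__ = ["Module", "Linear", "LayerNorm", "Dropout"]


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _collect(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _collect(item)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / math.sqrt(in_dim)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(out_dim,))) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta, eps=self.eps)


class Dropout(Module):
    def __init__(self, p: float):
        self.p = float(p)

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        return x.dropout(self.p, rng)
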