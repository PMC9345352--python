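"""Minimal layer framework for volumetric networks.

Tensors are ``float32`` numpy arrays laid out ``(N, C, D, H, W)``.  Every layer
is a :class:`Module` with an explicit ``forward``/``backward`` pair; forward
caches whatever backward needs.  Composite networks chain children by hand,
which keeps skip connections and gradient accumulation explicit and auditable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Module", "he_init", "new_rng"]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Param({self.name}, shape={self.data.shape})"


class Module:
    """Base class: owns parameters and optionally child modules."""

    training: bool = True

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in vars(self).values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in vars(self).values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = state[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data[...] = arr


def new_rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Kaiming-normal initialization for ReLU networks (float32 throughout,
    so very large fully-connected layers stay memory-friendly)."""
    std = np.float32(np.sqrt(2.0 / max(fan_in, 1)))
    out = rng.standard_normal(size=shape, dtype=np.float32)
    out *= std
    return out
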