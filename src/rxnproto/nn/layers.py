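"""Neural building blocks: linear/MLP layers, gated recurrent cells,
set2set pooling, dropout, and an Adam optimizer.

Initialization is Glorot-uniform from an explicit ``numpy.random.Generator``
so every model build is reproducible from a single integer seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module", "Linear", "MLP", "Dropout", "GRUCell", "LSTMCell", "Adam",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Tensor) and item.requires_grad and id(item) not in seen:
                    seen.add(id(item))
                    params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, arr in zip(params, state):
            p.data = np.asarray(arr, dtype=np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = glorot(rng, in_dim, out_dim)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; identity when `training` is False."""

    def __init__(self, p: float):
        self.p = float(p)
        self.training = False

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MLP(Module):
    """Feed-forward stack with ReLU between layers and optional dropout."""

    def __init__(self, dims: list[int], rng: np.random.Generator, dropout: float = 0.0):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
                x = self.drop(x, rng)
        return x

    def train(self, mode: bool = True) -> None:
        self.drop.training = mode


class GRUCell(Module):
    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.w_x = glorot(rng, input_dim, 3 * hidden_dim)
        self.w_h = glorot(rng, hidden_dim, 3 * hidden_dim)
        self.b_x = Tensor(np.zeros(3 * hidden_dim), requires_grad=True)
        self.b_h = Tensor(np.zeros(3 * hidden_dim), requires_grad=True)
        self.hidden_dim = hidden_dim

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        d = self.hidden_dim
        gx = x @ self.w_x + self.b_x
        gh = h @ self.w_h + self.b_h
        r = (gx[:, 0:d] + gh[:, 0:d]).sigmoid()
        z = (gx[:, d:2 * d] + gh[:, d:2 * d]).sigmoid()
        n = (gx[:, 2 * d:] + r * gh[:, 2 * d:]).tanh()
        return (1.0 - z) * n + z * h


class LSTMCell(Module):
    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.w_x = glorot(rng, input_dim, 4 * hidden_dim)
        self.w_h = glorot(rng, hidden_dim, 4 * hidden_dim)
        self.b = Tensor(np.zeros(4 * hidden_dim), requires_grad=True)
        self.hidden_dim = hidden_dim

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        d = self.hidden_dim
        g = x @ self.w_x + h @ self.w_h + self.b
        i = g[:, 0:d].sigmoid()
        f = g[:, d:2 * d].sigmoid()
        o = g[:, 2 * d:3 * d].sigmoid()
        u = g[:, 3 * d:].tanh()
        c_new = f * c + i * u
        h_new = o * c_new.tanh()
        return h_new, c_new


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
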