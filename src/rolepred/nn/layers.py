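"""Layers and optimizer built on the tape autodiff engine."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .autodiff import Tensor


class ParameterStore:
    """Named parameter registry with (de)serialization support."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}

    def add(self, name: str, value: np.ndarray) -> Tensor:
        if name in self._params:
            raise KeyError(f"duplicate parameter {name!r}")
        t = Tensor(np.asarray(value, dtype=np.float64), requires_grad=True)
        self._params[name] = t
        return t

    def __getitem__(self, name: str) -> Tensor:
        return self._params[name]

    def items(self):
        return self._params.items()

    def tensors(self, prefix: str | None = None) -> list[Tensor]:
        return [t for n, t in self._params.items() if prefix is None or n.startswith(prefix)]

    def zero_grad(self):
        for t in self._params.values():
            t.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: t.data.copy() for n, t in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self._params):
            missing = set(self._params) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for n, t in self._params.items():
            if t.data.shape != state[n].shape:
                raise ValueError(f"shape mismatch for {n!r}")
            t.data = np.asarray(state[n], dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class Linear:
    def __init__(self, store: ParameterStore, name: str, n_in: int, n_out: int,
                 rng: np.random.Generator, zero_init: bool = False):
        w = np.zeros((n_in, n_out)) if zero_init else _glorot(rng, n_in, n_out)
        self.W = store.add(f"{name}.W", w)
        self.b = store.add(f"{name}.b", np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LSTMCell:
    """Standard LSTM cell; gate order [i, f, g, o], forget bias +1."""

    def __init__(self, store: ParameterStore, name: str, n_in: int, n_hidden: int,
                 rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.Wx = store.add(f"{name}.Wx", _glorot(rng, n_in, 4 * n_hidden))
        self.Wh = store.add(f"{name}.Wh", _glorot(rng, n_hidden, 4 * n_hidden))
        b = np.zeros(4 * n_hidden)
        b[n_hidden: 2 * n_hidden] = 1.0
        self.b = store.add(f"{name}.b", b)

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = x @ self.Wx + h @ self.Wh + self.b
        H = self.n_hidden
        i = z.slice_cols(0, H).sigmoid()
        f = z.slice_cols(H, 2 * H).sigmoid()
        g = z.slice_cols(2 * H, 3 * H).tanh()
        o = z.slice_cols(3 * H, 4 * H).sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def step_masked(self, x: Tensor, h: Tensor, c: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        """Update only rows where mask==1 (mask shape (B, 1))."""
        h_new, c_new = self.step(x, h, c)
        m = Tensor(mask)
        keep = Tensor(1.0 - mask)
        return m * h_new + keep * h, m * c_new + keep * c

    def init_state(self, batch: int) -> tuple[Tensor, Tensor]:
        return Tensor(np.zeros((batch, self.n_hidden))), Tensor(np.zeros((batch, self.n_hidden)))


class Adam:
    def __init__(self, params: Iterable[Tensor], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
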