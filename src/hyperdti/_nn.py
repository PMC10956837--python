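"""Feed-forward building blocks and the Adam optimizer for the training core.

The encoders are plain MLPs (ReLU hidden activations, inter-layer dropout,
Xavier-uniform initialization) running in float32 on the autodiff core.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = ["MLP", "Adam"]


def _xavier_uniform(fan_in: int, fan_out: int, rng: np.random.Generator, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


class MLP:
    """Multi-layer perceptron ``input_dim -> hidden... -> out_dim``.

    Dropout (probability ``dropout``) is applied after each hidden
    activation, in training mode only; evaluation is deterministic.
    """

    def __init__(
        self,
        input_dim: int,
        hidden: tuple,
        out_dim: int,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        rng = rng or np.random.default_rng()
        self.dropout = float(dropout)
        self.dtype = dtype
        dims = [input_dim, *hidden, out_dim]
        self.weights = [
            Tensor(_xavier_uniform(a, b, rng, dtype), requires_grad=True)
            for a, b in zip(dims[:-1], dims[1:])
        ]
        self.biases = [
            Tensor(np.zeros(b, dtype=dtype), requires_grad=True) for b in dims[1:]
        ]

    @property
    def params(self) -> list:
        return [*self.weights, *self.biases]

    def __call__(self, x, train: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=self.dtype))
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                h = h.relu()
                if train and self.dropout > 0.0:
                    if rng is None:
                        raise ValueError("training-mode dropout needs an rng")
                    keep = (rng.random(h.shape) >= self.dropout).astype(self.dtype)
                    h = h * Tensor(keep / (1.0 - self.dropout))
        return h

    # ---- (de)serialization ----------------------------------------------
    def state_dict(self) -> dict:
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"w{i}"] = w.data
            out[f"b{i}"] = b.data
        return out

    def load_state_dict(self, state: dict) -> None:
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            w.data = np.asarray(state[f"w{i}"], dtype=self.dtype)
            b.data = np.asarray(state[f"b{i}"], dtype=self.dtype)


class Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(self, params: list, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
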