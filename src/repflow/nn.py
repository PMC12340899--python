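"""Feed-forward building blocks and the Adam optimizer.

Everything is float64 numpy under the hood (see ``repflow._autodiff``); all
parameter initialisation is driven by an explicit ``numpy.random.Generator``
so that training runs are bit-reproducible from a seed.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from ._autodiff import Tensor, tanh


class Linear:
    """Dense layer ``x @ W + b`` with Glorot-uniform initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            bound = np.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def parameters(self) -> List[Tensor]:
        return [self.W, self.b]


class MLP:
    """Multi-layer perceptron with tanh hidden activations and linear output.

    ``zero_init_output=True`` zeroes the final layer so the network starts as
    the constant-zero map — used to initialise flow conditioners at identity.
    """

    def __init__(self, n_in: int, hidden: Sequence[int], n_out: int,
                 rng: np.random.Generator, zero_init_output: bool = False):
        sizes = [n_in, *hidden, n_out]
        self.layers = []
        for i in range(len(sizes) - 1):
            last = i == len(sizes) - 2
            self.layers.append(Linear(sizes[i], sizes[i + 1], rng,
                                      zero_init=zero_init_output and last))

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i < len(self.layers) - 1:
                h = tanh(h)
        return h

    @property
    def parameters(self) -> List[Tensor]:
        return [p for l in self.layers for p in l.parameters]


class Adam:
    """Adam with optional decoupled L2 weight decay."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            if self.weight_decay:
                p.data = p.data * (1 - self.lr * self.weight_decay)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state(self):
        return {"m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v],
                "t": self.t}


def get_params_vector(params: Sequence[Tensor]) -> np.ndarray:
    return np.concatenate([p.data.ravel() for p in params])


def set_params_vector(params: Sequence[Tensor], vec: np.ndarray) -> None:
    i = 0
    for p in params:
        n = p.data.size
        p.data = vec[i:i + n].reshape(p.data.shape).copy()
        i += n


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Yield shuffled index arrays covering ``range(n)``."""
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]
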