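"""Minimal feed-forward building blocks: MLP, embedding table, Adam.

Everything is plain numpy with handwritten backpropagation; the networks
involved are small (two hidden layers, a 32-dim embedding) and run
comfortably on one CPU at the cohort sizes this package targets.
"""

from __future__ import annotations

import numpy as np


class MLP:
    """Fully connected stack with ReLU hidden layers.

    ``sizes`` gives layer widths input-first, e.g. ``[9, 64, 32, 32]``.
    ``sigmoid_out=True`` squashes the final layer into (0, 1).
    He-scaled Gaussian init; forward caches activations for backward.
    """

    def __init__(self, rng: np.random.Generator, sizes: list[int], sigmoid_out: bool = False):
        self.sizes = list(sizes)
        self.sigmoid_out = sigmoid_out
        self.Ws = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.bs = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.gWs: list[np.ndarray] = []
        self.gbs: list[np.ndarray] = []
        self._acts: list[np.ndarray] = []

    def params(self) -> list[np.ndarray]:
        return self.Ws + self.bs

    def grads(self) -> list[np.ndarray]:
        return self.gWs + self.gbs

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._acts = [x]
        h = x
        last = len(self.Ws) - 1
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            z = h @ W + b
            if i < last:
                h = np.maximum(z, 0.0)
            elif self.sigmoid_out:
                h = 1.0 / (1.0 + np.exp(-z))
            else:
                h = z
            self._acts.append(h)
        return h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Accumulate parameter grads for the cached batch; return grad wrt input."""
        g = grad_out
        n_layers = len(self.Ws)
        self.gWs = [np.empty(0)] * n_layers
        self.gbs = [np.empty(0)] * n_layers
        for i in range(n_layers - 1, -1, -1):
            h_out = self._acts[i + 1]
            if i < n_layers - 1:
                g = g * (h_out > 0)
            elif self.sigmoid_out:
                g = g * h_out * (1.0 - h_out)
            self.gWs[i] = self._acts[i].T @ g
            self.gbs[i] = g.sum(axis=0)
            g = g @ self.Ws[i].T
        return g

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_params(self, values: list[np.ndarray]) -> None:
        for p, val in zip(self.params(), values):
            p[...] = val


class Embedding:
    """Lookup table of latent vectors, one row per integer code."""

    def __init__(self, rng: np.random.Generator, n_rows: int, dim: int, scale: float = 0.1):
        self.table = rng.normal(0.0, scale, size=(n_rows, dim))
        self.gtable = np.zeros_like(self.table)
        self._idx: np.ndarray | None = None

    def forward(self, idx: np.ndarray) -> np.ndarray:
        self._idx = idx
        return self.table[idx]

    def backward(self, grad_out: np.ndarray) -> None:
        self.gtable = np.zeros_like(self.table)
        np.add.at(self.gtable, self._idx, grad_out)

    def params(self) -> list[np.ndarray]:
        return [self.table]

    def grads(self) -> list[np.ndarray]:
        return [self.gtable]


class Adam:
    """Adam with bias correction; state is per parameter array, in-place updates."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.beta1**self.t
        c2 = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
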