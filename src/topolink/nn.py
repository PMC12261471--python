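"""Neural-network building blocks on top of :mod:`topolink.autodiff`."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Linear", "BatchNorm1d", "Dropout", "he_init"]


def he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 zero_init: bool = False):
        w = np.zeros((in_dim, out_dim)) if zero_init else he_init(rng, in_dim, out_dim)
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class BatchNorm1d:
    """Batch normalization over the row (sample) axis with running statistics.

    The models here train full-batch (every node of the graph in each step),
    so the batch statistics ARE the population statistics; the default
    momentum of 1.0 makes evaluation use the statistics of the latest
    training epoch instead of a slowly warming running average.
    """

    def __init__(self, dim: int, momentum: float = 1.0, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def __call__(self, x: Tensor, train_mode: bool) -> Tensor:
        if train_mode:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - self.running_mean) * ((self.running_var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class Dropout:
    """Inverted dropout; active only in train mode, seeded via the caller's rng."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, train_mode: bool, rng: np.random.Generator) -> Tensor:
        if not train_mode or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)
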