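"""Dense layers, multilayer perceptrons and the Adam optimizer used by both
encoder paths (graph network and fingerprint autoencoder)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad

__all__ = ["glorot", "Linear", "MLP", "Adam"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class Linear:
    """Affine map x @ W + b.  Set ``bias=False`` for a pure linear map."""

    weight: ad.Tensor
    bias: ad.Tensor | None = None

    @classmethod
    def init(cls, rng: np.random.Generator, n_in: int, n_out: int, bias: bool = True) -> "Linear":
        w = ad.parameter(glorot(rng, n_in, n_out))
        b = ad.parameter(np.zeros(n_out)) if bias else None
        return cls(w, b)

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = ad.add(out, self.bias)
        return out

    @property
    def parameters(self) -> list[ad.Tensor]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])


@dataclass
class MLP:
    """Feed-forward stack: rectifier between layers, linear final layer.

    ``dropout`` (inverted dropout on hidden activations) is applied only when
    a training ``rng`` is passed to ``__call__``; evaluation is deterministic.
    """

    layers: list[Linear]
    dropout: float = 0.0

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        sizes: list[int],
        dropout: float = 0.0,
    ) -> "MLP":
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        layers = [Linear.init(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])]
        return cls(layers, dropout)

    def __call__(self, x: ad.Tensor, rng: np.random.Generator | None = None) -> ad.Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = ad.relu(x)
                if self.dropout > 0.0 and rng is not None:
                    keep = 1.0 - self.dropout
                    mask = (rng.random(x.data.shape) < keep) / keep
                    x = ad.mul(x, ad.constant(mask))
        return x

    @property
    def parameters(self) -> list[ad.Tensor]:
        return [p for layer in self.layers for p in layer.parameters]

    @property
    def sizes(self) -> list[int]:
        s = [l.weight.data.shape[0] for l in self.layers]
        s.append(self.layers[-1].weight.data.shape[1])
        return s


@dataclass
class Adam:
    """Adaptive-moment estimation with bias correction."""

    params: list[ad.Tensor]
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: list[np.ndarray] = field(init=False)
    _v: list[np.ndarray] = field(init=False)
    _t: int = field(init=False, default=0)

    def __post_init__(self):
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / (1 - b1**self._t)
            v_hat = self._v[i] / (1 - b2**self._t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
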