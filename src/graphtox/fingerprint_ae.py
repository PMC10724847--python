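"""Fingerprint autoencoder path: a deep autoencoder compresses binary
topological fingerprints to a low-dimensional latent code (pretrained on an
unlabeled compound pool), and a feed-forward head classifies the code.

The decoder mirrors the encoder; hidden layers use the rectifier, the
reconstruction layer is logistic so outputs lie in [0,1] against the binary
targets, and the training loss is mean squared error.  The validation side
of the supplied split monitors reconstruction under whatever distribution
shift the split strategy induces (random, scaffold, weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .chemio import Fingerprint
from .dmpnn import ClassifierHead
from .nn import Adam, Linear
from .splitters import SplitResult

__all__ = ["AEConfig", "AEParams", "LossHistory", "train_autoencoder", "encode", "encode_matrix", "classify_latent", "fingerprint_matrix"]


@dataclass(frozen=True)
class AEConfig:
    """Autoencoder architecture and training settings.

    ``hidden_sizes`` are the encoder's intermediate widths; the decoder is
    the mirror image.  Default stack 2048 -> 1024 -> 512 -> 256 latent.
    """

    n_bits: int = 2048
    hidden_sizes: tuple[int, ...] = (1024, 512)
    latent_dim: int = 256
    epochs: int = 30
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim >= self.n_bits:
            raise ValueError("latent dimension must be smaller than the input")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class AEParams:
    encoder: list[Linear]
    decoder: list[Linear]
    n_bits: int
    latent_dim: int

    @classmethod
    def init(cls, cfg: AEConfig, rng: np.random.Generator) -> "AEParams":
        sizes = [cfg.n_bits, *cfg.hidden_sizes, cfg.latent_dim]
        encoder = [Linear.init(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])]
        rev = sizes[::-1]
        decoder = [Linear.init(rng, a, b) for a, b in zip(rev[:-1], rev[1:])]
        return cls(encoder, decoder, cfg.n_bits, cfg.latent_dim)

    @property
    def parameters(self) -> list[ad.Tensor]:
        return [p for layer in self.encoder + self.decoder for p in layer.parameters]

    def encode_t(self, x: ad.Tensor) -> ad.Tensor:
        for layer in self.encoder:
            x = ad.relu(layer(x))
        return x

    def reconstruct_t(self, x: ad.Tensor) -> ad.Tensor:
        z = self.encode_t(x)
        for layer in self.decoder[:-1]:
            z = ad.relu(layer(z))
        return ad.sigmoid(self.decoder[-1](z))


@dataclass
class LossHistory:
    """Per-epoch train/validation reconstruction MSE."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_mse)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_mse) + 1),
                "train_mse": self.train_mse,
                "val_mse": self.val_mse,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def fingerprint_matrix(fps: list[Fingerprint]) -> np.ndarray:
    """Stack fingerprints into a float (n, n_bits) matrix."""
    if not fps:
        raise ValueError("no fingerprints given")
    n_bits = fps[0].n_bits
    if any(fp.n_bits != n_bits for fp in fps):
        raise ValueError("fingerprints have inconsistent n_bits")
    return np.stack([fp.bits for fp in fps]).astype(np.float64)


def _reconstruction_mse(params: AEParams, x: np.ndarray) -> float:
    recon = params.reconstruct_t(ad.constant(x))
    return float(np.mean((recon.data - x) ** 2))


def train_autoencoder(
    fps: list[Fingerprint],
    split: SplitResult,
    cfg: AEConfig,
) -> tuple[AEParams, LossHistory]:
    """Pretrain the autoencoder on the split's train side, monitoring
    reconstruction MSE on the split's test side each epoch.

    Deterministic for a given config/seed.  ``epochs=0`` returns freshly
    initialized parameters and an empty history.
    """
    x = fingerprint_matrix(fps)
    if x.shape[1] != cfg.n_bits:
        raise ValueError(f"fingerprints have {x.shape[1]} bits, config expects {cfg.n_bits}")
    train_idx = np.asarray(split.train_idx, dtype=np.intp)
    val_idx = np.asarray(split.test_idx, dtype=np.intp)
    if len(train_idx) < 2 or len(val_idx) < 2:
        raise ValueError("need at least 2 fingerprints on each split side")
    x_train, x_val = x[train_idx], x[val_idx]

    rng = np.random.default_rng(cfg.seed)
    params = AEParams.init(cfg, rng)
    opt = Adam(params.parameters, lr=cfg.lr)
    history = LossHistory()

    n = len(x_train)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = x_train[order[start : start + cfg.batch_size]]
            recon = params.reconstruct_t(ad.constant(batch))
            loss = ad.mse(recon, batch)
            opt.zero_grad()
            loss.backward()
            opt.step()
        history.train_mse.append(_reconstruction_mse(params, x_train))
        history.val_mse.append(_reconstruction_mse(params, x_val))
    return params, history


def encode(fp: Fingerprint, params: AEParams) -> np.ndarray:
    """Latent code for one fingerprint."""
    if fp.n_bits != params.n_bits:
        raise ValueError(f"fingerprint has {fp.n_bits} bits, encoder expects {params.n_bits}")
    return encode_matrix(fp.bits[None, :].astype(np.float64), params)[0]


def encode_matrix(x: np.ndarray, params: AEParams) -> np.ndarray:
    """Latent codes for a (n, n_bits) matrix."""
    if x.shape[1] != params.n_bits:
        raise ValueError("input width does not match encoder")
    return params.encode_t(ad.constant(x)).data


def classify_latent(latent: np.ndarray, head: ClassifierHead) -> float:
    """Probability in (0,1) from the feed-forward head on a latent code."""
    return float(head.predict_proba(np.atleast_2d(latent))[0])
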