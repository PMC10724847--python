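"""Model/Results surface for the two encoder paths.

Mirrors the fit-object convention of statistical modelling packages: a model
object is constructed from a dataset, ``fit()`` runs the optimization and
returns a Results object carrying the trained parameters, loss history,
evaluation methods and a ``summary()`` table.

- :class:`GraphClassifier` - directed-edge message-passing encoder + head.
- :class:`FingerprintAutoencoder` - fingerprint-compression pretrainer.
- :class:`FingerprintClassifier` - feed-forward head on autoencoder codes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chemio import DatasetTable, Fingerprint, parse_smiles, topological_fingerprint
from .fingerprint_ae import (
    AEConfig,
    AEParams,
    LossHistory,
    encode_matrix,
    fingerprint_matrix,
    train_autoencoder,
)
from .molgraph import FeatureVocab, featurize
from .splitters import SplitResult, SplitSpec, make_split, random_split
from .training import (
    CVResult,
    MetricsRecord,
    ModelBundle,
    TrainConfig,
    bundle_ae_ffnn,
    bundle_gnn,
    cross_validate,
    evaluate_holdout,
    predict_rank,
    train_gnn_classifier,
    train_latent_classifier,
)

__all__ = ["GraphClassifier", "FingerprintAutoencoder", "FingerprintClassifier", "ClassifierResults", "AutoencoderResults"]


@dataclass
class ClassifierResults:
    """Fitted classifier: trained bundle, loss history and evaluation API."""

    bundle: ModelBundle
    loss_history: list[float]
    endpoint: str
    train_metrics: MetricsRecord | None = None

    def predict(self, smiles_list: list[str], min_prob: float | None = None) -> pd.DataFrame:
        frame, failures = predict_rank(self.bundle, smiles_list, min_prob=min_prob)
        frame.attrs["failures"] = failures
        return frame

    def evaluate(self, data: DatasetTable, endpoint: str | None = None) -> MetricsRecord:
        return evaluate_holdout(self.bundle, data, endpoint or self.endpoint)

    def summary(self) -> str:
        lines = [
            f"{'Model:':<22}{self.bundle.model_type}",
            f"{'Endpoint:':<22}{self.endpoint}",
            f"{'Decision threshold:':<22}{self.bundle.threshold}",
            f"{'Epochs run:':<22}{len(self.loss_history)}",
        ]
        if self.loss_history:
            lines.append(f"{'Final train loss:':<22}{self.loss_history[-1]:.4f}")
        if self.train_metrics is not None:
            lines.append(f"{'Train accuracy:':<22}{self.train_metrics.accuracy:.4f}")
            lines.append(f"{'Train ROC-AUC:':<22}{self.train_metrics.roc_auc:.4f}")
        return "\n".join(lines)


class GraphClassifier:
    """Per-endpoint binary classifier on the directed-edge graph encoding.

    Parameters mirror the encoder defaults (hidden width 300, depth 3, one
    hidden head layer of 300); all are overridable.  ``fit`` trains with
    masked binary cross-entropy and Adam.
    """

    def __init__(
        self,
        data: DatasetTable,
        endpoint: str,
        *,
        hidden: int = 300,
        depth: int = 3,
        head_hidden: tuple[int, ...] = (300,),
        dropout: float = 0.0,
        aggregation: str = "sum",
        vocab: FeatureVocab | None = None,
    ):
        if endpoint not in data.endpoint_names:
            raise ValueError(f"endpoint {endpoint!r} not in dataset")
        self.data = data
        self.endpoint = endpoint
        self.vocab = vocab or FeatureVocab()
        self._cfg = TrainConfig(
            model="gnn",
            endpoint=endpoint,
            hidden=hidden,
            depth=depth,
            head_hidden=head_hidden,
            dropout=dropout,
            aggregation=aggregation,
        )

    def fit(
        self,
        *,
        epochs: int = 20,
        batch_size: int = 50,
        lr: float = 1e-3,
        seed: int = 0,
        threshold: float = 0.5,
    ) -> ClassifierResults:
        cfg = replace(
            self._cfg, epochs=epochs, batch_size=batch_size, lr=lr, seed=seed, threshold=threshold
        )
        graphs = [featurize(m, self.vocab) for m in self.data.molecules]
        labels = self.data.labels_array(self.endpoint)
        params, head, losses = train_gnn_classifier(graphs, labels, cfg, self.vocab)
        bundle = bundle_gnn(params, head, self.vocab, cfg)
        res = ClassifierResults(bundle=bundle, loss_history=losses, endpoint=self.endpoint)
        res.train_metrics = evaluate_holdout(bundle, self.data, self.endpoint)
        return res

    def fit_cv(self, *, k: int = 5, epochs: int = 20, batch_size: int = 50, lr: float = 1e-3, seed: int = 0) -> CVResult:
        """k-fold cross-validation (the workflow used for model selection)."""
        cfg = replace(self._cfg, k=k, epochs=epochs, batch_size=batch_size, lr=lr, seed=seed)
        return cross_validate(self.data, cfg)


@dataclass
class AutoencoderResults:
    """Fitted autoencoder: parameters, loss history, encoding API."""

    params: AEParams
    loss_history: LossHistory
    split: SplitResult

    @property
    def final_val_mse(self) -> float:
        return self.loss_history.val_mse[-1] if len(self.loss_history) else float("nan")

    def encode(self, fps: list[Fingerprint]) -> np.ndarray:
        return encode_matrix(fingerprint_matrix(fps), self.params)

    def encode_smiles(self, smiles_list: list[str]) -> np.ndarray:
        fps = [topological_fingerprint(parse_smiles(s), self.params.n_bits) for s in smiles_list]
        return self.encode(fps)

    def summary(self) -> str:
        lines = [
            f"{'Model:':<22}fingerprint autoencoder",
            f"{'Input bits:':<22}{self.params.n_bits}",
            f"{'Latent dim:':<22}{self.params.latent_dim}",
            f"{'Epochs run:':<22}{len(self.loss_history)}",
        ]
        if len(self.loss_history):
            lines.append(f"{'Final train MSE:':<22}{self.loss_history.train_mse[-1]:.4f}")
            lines.append(f"{'Final val MSE:':<22}{self.loss_history.val_mse[-1]:.4f}")
        return "\n".join(lines)


class FingerprintAutoencoder:
    """Deep autoencoder over binary topological fingerprints.

    Built from an unlabeled SMILES pool (or precomputed fingerprints); the
    validation side of the chosen split strategy monitors reconstruction
    under the induced distribution shift.
    """

    def __init__(
        self,
        smiles_or_fps: list,
        *,
        n_bits: int = 2048,
        hidden_sizes: tuple[int, ...] = (1024, 512),
        latent_dim: int = 256,
    ):
        if not smiles_or_fps:
            raise ValueError("need at least one input structure")
        if isinstance(smiles_or_fps[0], Fingerprint):
            self.fingerprints = list(smiles_or_fps)
            self.molecules = None
        else:
            self.molecules = [parse_smiles(s) for s in smiles_or_fps]
            self.fingerprints = [topological_fingerprint(m, n_bits) for m in self.molecules]
        self.n_bits = self.fingerprints[0].n_bits
        self.hidden_sizes = hidden_sizes
        self.latent_dim = latent_dim

    def fit(
        self,
        *,
        split: SplitResult | SplitSpec | None = None,
        epochs: int = 30,
        batch_size: int = 64,
        lr: float = 1e-3,
        seed: int = 0,
    ) -> AutoencoderResults:
        if split is None:
            split = random_split(len(self.fingerprints), SplitSpec("random", 0.9, seed=seed))
        elif isinstance(split, SplitSpec):
            if split.strategy != "random" and self.molecules is None:
                raise ValueError("structure-based splits need SMILES inputs, not raw fingerprints")
            split = (
                random_split(len(self.fingerprints), split)
                if split.strategy == "random"
                else make_split(self.molecules, split)
            )
        cfg = AEConfig(
            n_bits=self.n_bits,
            hidden_sizes=self.hidden_sizes,
            latent_dim=self.latent_dim,
            epochs=epochs,
            batch_size=batch_size,
            lr=lr,
            seed=seed,
        )
        params, history = train_autoencoder(self.fingerprints, split, cfg)
        return AutoencoderResults(params=params, loss_history=history, split=split)


class FingerprintClassifier:
    """Feed-forward classifier on autoencoder latent codes (the legacy
    fingerprint path).  Supply a fitted :class:`AutoencoderResults` (frozen
    encoder, the default workflow) or let ``fit`` pretrain one on the
    training fingerprints."""

    def __init__(
        self,
        data: DatasetTable,
        endpoint: str,
        *,
        encoder: AutoencoderResults | AEParams | None = None,
        n_bits: int = 2048,
        head_hidden: tuple[int, ...] = (300,),
        dropout: float = 0.0,
        ae_hidden: tuple[int, ...] = (1024, 512),
        latent_dim: int = 256,
    ):
        if endpoint not in data.endpoint_names:
            raise ValueError(f"endpoint {endpoint!r} not in dataset")
        self.data = data
        self.endpoint = endpoint
        if isinstance(encoder, AutoencoderResults):
            encoder = encoder.params
        self.encoder = encoder
        n_bits = encoder.n_bits if encoder is not None else n_bits
        self._cfg = TrainConfig(
            model="ae+ffnn",
            endpoint=endpoint,
            n_bits=n_bits,
            head_hidden=head_hidden,
            dropout=dropout,
            ae_hidden=ae_hidden,
            latent_dim=encoder.latent_dim if encoder is not None else latent_dim,
        )

    def fit(
        self,
        *,
        epochs: int = 20,
        batch_size: int = 50,
        lr: float = 1e-3,
        seed: int = 0,
        threshold: float = 0.5,
        ae_epochs: int = 10,
    ) -> ClassifierResults:
        cfg = replace(
            self._cfg,
            epochs=epochs,
            batch_size=batch_size,
            lr=lr,
            seed=seed,
            threshold=threshold,
            ae_epochs=ae_epochs,
        )
        fps = [topological_fingerprint(m, cfg.n_bits) for m in self.data.molecules]
        x = fingerprint_matrix(fps)
        encoder = self.encoder
        if encoder is None:
            inner = random_split(len(fps), SplitSpec("random", 0.9, seed=seed))
            encoder, _ = train_autoencoder(fps, inner, cfg.ae_config())
        labels = self.data.labels_array(self.endpoint)
        z = encode_matrix(x, encoder)
        head, losses = train_latent_classifier(z, labels, cfg)
        bundle = bundle_ae_ffnn(encoder, head, cfg)
        res = ClassifierResults(bundle=bundle, loss_history=losses, endpoint=self.endpoint)
        res.train_metrics = evaluate_holdout(bundle, self.data, self.endpoint)
        return res

    def fit_cv(self, *, k: int = 5, epochs: int = 20, batch_size: int = 50, lr: float = 1e-3, seed: int = 0, ae_epochs: int = 10) -> CVResult:
        cfg = replace(self._cfg, k=k, epochs=epochs, batch_size=batch_size, lr=lr, seed=seed, ae_epochs=ae_epochs)
        return cross_validate(self.data, cfg, ae_params=self.encoder)
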