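"""Training orchestration: evaluation metrics, per-endpoint k-fold
cross-validation for both encoder paths, model serialization, and bulk
ranked prediction for screening.

Missing labels are masked out of both the loss and the metrics, never
imputed.  All randomness flows from one root seed through named substreams
(fold assignment, parameter init, batch shuffling), so every result is
replayable.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import autodiff as ad
from .chemio import (
    DatasetTable,
    Molecule,
    SmilesParseError,
    parse_smiles,
    topological_fingerprint,
)
from .dmpnn import ClassifierHead, DMPNNParams, GraphBatch, encode_batch
from .fingerprint_ae import AEConfig, AEParams, encode_matrix, fingerprint_matrix
from .molgraph import FeatureVocab, featurize
from .nn import MLP, Adam, Linear
from .splitters import kfold_assign

__all__ = [
    "UndefinedMetricError",
    "TrainConfig",
    "MetricsRecord",
    "CVResult",
    "ModelBundle",
    "binary_accuracy",
    "roc_auc",
    "cross_validate",
    "evaluate_holdout",
    "predict_rank",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. single-class ROC-AUC)."""


def _substream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(tag)])


# ---------------------------------------------------------------------------
# Metrics


def binary_accuracy(probs, labels, threshold: float = 0.5) -> float:
    """Fraction of predictions where (prob >= threshold) matches the label."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.shape != labels.shape or probs.size == 0:
        raise ValueError("probs and labels must be equal-length and non-empty")
    return float(np.mean((probs >= threshold) == (labels == 1.0)))


def roc_auc(scores, labels) -> float:
    """Mann-Whitney ROC-AUC: probability a random positive outscores a
    random negative, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    pos = labels == 1.0
    n_pos = int(pos.sum())
    n_neg = int(scores.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC-AUC undefined: only one class present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class TrainConfig:
    """Settings for one per-endpoint training run."""

    model: str = "gnn"  # gnn | ae+ffnn
    endpoint: str = "activity"
    k: int = 5
    epochs: int = 20
    batch_size: int = 50
    lr: float = 1e-3
    seed: int = 0
    threshold: float = 0.5
    # graph path
    hidden: int = 300
    depth: int = 3
    head_hidden: tuple[int, ...] = (300,)
    dropout: float = 0.0
    aggregation: str = "sum"
    # fingerprint path
    n_bits: int = 2048
    ae_hidden: tuple[int, ...] = (1024, 512)
    latent_dim: int = 256
    ae_epochs: int = 10

    def __post_init__(self):
        if self.model not in ("gnn", "ae+ffnn"):
            raise ValueError(f"unknown model path {self.model!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")

    def ae_config(self, seed: int | None = None) -> AEConfig:
        return AEConfig(
            n_bits=self.n_bits,
            hidden_sizes=self.ae_hidden,
            latent_dim=self.latent_dim,
            epochs=self.ae_epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            seed=self.seed if seed is None else seed,
        )


@dataclass
class MetricsRecord:
    """Accuracy and ROC-AUC over the non-missing labels of one evaluation."""

    accuracy: float
    roc_auc: float
    n: int

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "roc_auc": self.roc_auc, "n": self.n}


@dataclass
class CVResult:
    """Per-fold metrics, their mean, the best fold, and trained bundles."""

    folds: pd.DataFrame  # columns: fold, accuracy, roc_auc, n
    best_fold: int
    bundles: list["ModelBundle"]
    config: TrainConfig

    @property
    def mean_accuracy(self) -> float:
        return float(self.folds["accuracy"].mean())

    @property
    def mean_roc_auc(self) -> float:
        return float(self.folds["roc_auc"].mean())

    @property
    def best_bundle(self) -> "ModelBundle":
        return self.bundles[self.best_fold]

    def summary_json(self) -> dict:
        return {
            "model": self.config.model,
            "endpoint": self.config.endpoint,
            "k": self.config.k,
            "per_fold": self.folds.to_dict(orient="records"),
            "mean_accuracy": self.mean_accuracy,
            "mean_roc_auc": self.mean_roc_auc,
            "best_fold": self.best_fold,
        }


# ---------------------------------------------------------------------------
# Model bundle (portable trained model)


@dataclass
class ModelBundle:
    """Trained parameters + featurization config + decision threshold,
    serializable as a single archive for the predict command."""

    model_type: str  # gnn | ae+ffnn
    config: dict
    arrays: dict[str, np.ndarray]

    def save(self, path: str | Path) -> None:
        buf = io.BytesIO()
        np.savez(buf, **self.arrays)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps({"model_type": self.model_type, **self.config}))
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        with zipfile.ZipFile(path) as zf:
            cfg = json.loads(zf.read("config.json"))
            with np.load(io.BytesIO(zf.read("params.npz"))) as npz:
                arrays = {k: npz[k] for k in npz.files}
        model_type = cfg.pop("model_type")
        return cls(model_type=model_type, config=cfg, arrays=arrays)

    # -- reconstruction of live objects -----------------------------------

    def _head(self) -> ClassifierHead:
        layers = []
        i = 0
        while f"head_W{i}" in self.arrays:
            layers.append(
                Linear(ad.Tensor(self.arrays[f"head_W{i}"]), ad.Tensor(self.arrays[f"head_b{i}"]))
            )
            i += 1
        return ClassifierHead(MLP(layers, dropout=0.0))

    def _gnn_params(self) -> tuple[DMPNNParams, FeatureVocab]:
        vocab = FeatureVocab.from_json(self.config["vocab"])
        p = DMPNNParams(
            W_input=ad.Tensor(self.arrays["W_input"]),
            W_message=ad.Tensor(self.arrays["W_message"]),
            readout_layer=Linear(ad.Tensor(self.arrays["readout_W"]), ad.Tensor(self.arrays["readout_b"])),
            depth=int(self.config["depth"]),
            hidden=int(self.config["hidden"]),
            aggregation=self.config.get("aggregation", "sum"),
        )
        return p, vocab

    def _ae_params(self) -> AEParams:
        enc, dec = [], []
        i = 0
        while f"enc_W{i}" in self.arrays:
            enc.append(Linear(ad.Tensor(self.arrays[f"enc_W{i}"]), ad.Tensor(self.arrays[f"enc_b{i}"])))
            i += 1
        i = 0
        while f"dec_W{i}" in self.arrays:
            dec.append(Linear(ad.Tensor(self.arrays[f"dec_W{i}"]), ad.Tensor(self.arrays[f"dec_b{i}"])))
            i += 1
        return AEParams(enc, dec, int(self.config["n_bits"]), int(self.config["latent_dim"]))

    def predict_proba_molecules(self, mols: list[Molecule]) -> np.ndarray:
        """Evaluation-mode probabilities for parsed molecules."""
        if not mols:
            return np.zeros(0)
        head = self._head()
        if self.model_type == "gnn":
            p, vocab = self._gnn_params()
            batch = GraphBatch.from_graphs([featurize(m, vocab) for m in mols])
            emb = encode_batch(batch, p).data
            return head.predict_proba(emb)
        fps = [topological_fingerprint(m, int(self.config["n_bits"])) for m in mols]
        latents = encode_matrix(fingerprint_matrix(fps), self._ae_params())
        return head.predict_proba(latents)

    @property
    def threshold(self) -> float:
        return float(self.config.get("threshold", 0.5))


def _head_arrays(head: ClassifierHead) -> dict[str, np.ndarray]:
    out = {}
    for i, layer in enumerate(head.mlp.layers):
        out[f"head_W{i}"] = layer.weight.data.copy()
        out[f"head_b{i}"] = layer.bias.data.copy()
    return out


def bundle_gnn(p: DMPNNParams, head: ClassifierHead, vocab: FeatureVocab, cfg: TrainConfig) -> ModelBundle:
    arrays = {
        "W_input": p.W_input.data.copy(),
        "W_message": p.W_message.data.copy(),
        "readout_W": p.readout_layer.weight.data.copy(),
        "readout_b": p.readout_layer.bias.data.copy(),
        **_head_arrays(head),
    }
    config = {
        "vocab": vocab.to_json(),
        "depth": p.depth,
        "hidden": p.hidden,
        "aggregation": p.aggregation,
        "threshold": cfg.threshold,
        "endpoint": cfg.endpoint,
        "train_config": _config_fingerprint(cfg),
    }
    return ModelBundle("gnn", config, arrays)


def bundle_ae_ffnn(ae: AEParams, head: ClassifierHead, cfg: TrainConfig) -> ModelBundle:
    arrays = {}
    for i, layer in enumerate(ae.encoder):
        arrays[f"enc_W{i}"] = layer.weight.data.copy()
        arrays[f"enc_b{i}"] = layer.bias.data.copy()
    for i, layer in enumerate(ae.decoder):
        arrays[f"dec_W{i}"] = layer.weight.data.copy()
        arrays[f"dec_b{i}"] = layer.bias.data.copy()
    arrays.update(_head_arrays(head))
    config = {
        "n_bits": ae.n_bits,
        "latent_dim": ae.latent_dim,
        "threshold": cfg.threshold,
        "endpoint": cfg.endpoint,
        "train_config": _config_fingerprint(cfg),
    }
    return ModelBundle("ae+ffnn", config, arrays)


def _config_fingerprint(cfg: TrainConfig) -> dict:
    d = {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
    d["head_hidden"] = list(cfg.head_hidden)
    d["ae_hidden"] = list(cfg.ae_hidden)
    return d


# ---------------------------------------------------------------------------
# Supervised training loops (masked binary cross-entropy)


def train_gnn_classifier(
    graphs: list,
    labels: np.ndarray,
    cfg: TrainConfig,
    vocab: FeatureVocab,
    seed: int | None = None,
) -> tuple[DMPNNParams, ClassifierHead, list[float]]:
    """Train the graph path on featurized graphs with NaN-masked labels.

    Returns encoder params, head, and the per-epoch mean training loss.
    """
    seed = cfg.seed if seed is None else seed
    rng_init = _substream(seed, 1)
    rng_shuffle = _substream(seed, 2)
    params = DMPNNParams.init(rng_init, vocab, hidden=cfg.hidden, depth=cfg.depth, aggregation=cfg.aggregation)
    head = ClassifierHead.init(rng_init, cfg.hidden, cfg.head_hidden, cfg.dropout)
    opt = Adam(params.parameters + head.parameters, lr=cfg.lr)

    labeled = np.flatnonzero(~np.isnan(labels))
    if labeled.size == 0:
        raise ValueError("no non-missing labels to train on")
    losses = []
    for _ in range(cfg.epochs):
        order = rng_shuffle.permutation(labeled)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, order.size, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = GraphBatch.from_graphs([graphs[i] for i in idx])
            emb = encode_batch(batch, params)
            logits = head.logits(emb, rng=rng_shuffle if cfg.dropout > 0 else None)
            y = labels[idx][:, None]
            loss = ad.bce_with_logits(logits, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
    return params, head, losses


def train_latent_classifier(
    latents: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    seed: int | None = None,
) -> tuple[ClassifierHead, list[float]]:
    """Train the feed-forward head on autoencoder latent codes."""
    seed = cfg.seed if seed is None else seed
    rng_init = _substream(seed, 3)
    rng_shuffle = _substream(seed, 4)
    head = ClassifierHead.init(rng_init, latents.shape[1], cfg.head_hidden, cfg.dropout)
    opt = Adam(head.parameters, lr=cfg.lr)
    labeled = np.flatnonzero(~np.isnan(labels))
    if labeled.size == 0:
        raise ValueError("no non-missing labels to train on")
    losses = []
    for _ in range(cfg.epochs):
        order = rng_shuffle.permutation(labeled)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, order.size, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = head.logits(ad.constant(latents[idx]), rng=rng_shuffle if cfg.dropout > 0 else None)
            loss = ad.bce_with_logits(logits, labels[idx][:, None])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
    return head, losses


# ---------------------------------------------------------------------------
# Cross-validation and evaluation


def _check_class_counts(labels: np.ndarray, k: int, endpoint: str) -> None:
    n_pos = int(np.nansum(labels == 1.0))
    n_neg = int(np.nansum(labels == 0.0))
    if n_pos < k or n_neg < k:
        raise ValueError(
            f"endpoint {endpoint!r} needs >= {k} examples of each class for "
            f"{k}-fold cross-validation (got {n_pos} positive, {n_neg} negative)"
        )


def cross_validate(data: DatasetTable, cfg: TrainConfig, ae_params: AEParams | None = None) -> CVResult:
    """k-fold cross-validation of one endpoint with the configured model path.

    Each fold trains on its train side and is evaluated on its validation
    side (non-missing labels only); the best fold maximizes validation
    ROC-AUC, ties resolved toward the lower fold index.  For the
    fingerprint path, a pretrained autoencoder may be supplied; otherwise
    one is trained on the fold-train fingerprints.
    """
    if cfg.endpoint not in data.endpoint_names:
        raise ValueError(f"endpoint {cfg.endpoint!r} not present in dataset")
    labels = data.labels_array(cfg.endpoint)
    _check_class_counts(labels, cfg.k, cfg.endpoint)
    folds = kfold_assign(len(data), cfg.k, seed=int(_substream(cfg.seed, 0).integers(2**31)))

    vocab = FeatureVocab()
    graphs = latents = None
    if cfg.model == "gnn":
        graphs = [featurize(m, vocab) for m in data.molecules]
    else:
        fps = [topological_fingerprint(m, cfg.n_bits) for m in data.molecules]
        x = fingerprint_matrix(fps)

    rows, bundles = [], []
    for fold_i, (train_idx, val_idx) in enumerate(folds):
        train_idx = np.asarray(train_idx)
        val_idx = np.asarray(val_idx)
        fold_seed = int(_substream(cfg.seed, 100 + fold_i).integers(2**31))
        if cfg.model == "gnn":
            fold_graphs = [graphs[i] for i in train_idx]
            p, head, _ = train_gnn_classifier(fold_graphs, labels[train_idx], cfg, vocab, seed=fold_seed)
            bundle = bundle_gnn(p, head, vocab, cfg)
        else:
            if ae_params is None:
                from .fingerprint_ae import train_autoencoder
                from .splitters import SplitResult, random_split, SplitSpec

                inner = random_split(len(train_idx), SplitSpec("random", 0.9, seed=fold_seed))
                fold_ae, _ = train_autoencoder(
                    [fps[i] for i in train_idx], inner, cfg.ae_config(seed=fold_seed)
                )
            else:
                fold_ae = ae_params
            z = encode_matrix(x, fold_ae)
            head, _ = train_latent_classifier(z[train_idx], labels[train_idx], cfg, seed=fold_seed)
            bundle = bundle_ae_ffnn(fold_ae, head, cfg)

        probs = bundle.predict_proba_molecules([data.records[i].molecule for i in val_idx])
        mask = ~np.isnan(labels[val_idx])
        if mask.sum() == 0:
            raise ValueError("validation fold has no non-missing labels")
        y, pr = labels[val_idx][mask], probs[mask]
        rows.append(
            {
                "fold": fold_i,
                "accuracy": binary_accuracy(pr, y, cfg.threshold),
                "roc_auc": roc_auc(pr, y),
                "n": int(mask.sum()),
            }
        )
        bundles.append(bundle)

    frame = pd.DataFrame(rows)
    best = int(frame["roc_auc"].idxmax())  # idxmax returns the first maximum
    return CVResult(folds=frame, best_fold=best, bundles=bundles, config=cfg)


def evaluate_holdout(bundle: ModelBundle, data: DatasetTable, endpoint: str) -> MetricsRecord:
    """Metrics of a trained bundle on the non-missing labels of a dataset."""
    labels = data.labels_array(endpoint)
    mask = ~np.isnan(labels)
    if mask.sum() == 0:
        raise ValueError(f"no non-missing labels for endpoint {endpoint!r}")
    mols = [r.molecule for r, m in zip(data.records, mask) if m]
    probs = bundle.predict_proba_molecules(mols)
    y = labels[mask]
    return MetricsRecord(
        accuracy=binary_accuracy(probs, y, bundle.threshold),
        roc_auc=roc_auc(probs, y),
        n=int(mask.sum()),
    )


def predict_rank(
    bundle: ModelBundle,
    smiles_list: list[str],
    min_prob: float | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank inputs by predicted probability (descending; ties keep input
    order).  Unparseable SMILES are returned separately, never dropped
    silently.  ``min_prob`` keeps only rows with probability above it."""
    mols, kept_smiles, failures = [], [], []
    for smi in smiles_list:
        try:
            mols.append(parse_smiles(smi))
            kept_smiles.append(smi)
        except SmilesParseError:
            failures.append(smi)
    probs = bundle.predict_proba_molecules(mols)
    frame = pd.DataFrame({"smiles": kept_smiles, "probability": probs})
    frame = frame.sort_values("probability", ascending=False, kind="stable").reset_index(drop=True)
    if min_prob is not None:
        frame = frame[frame["probability"] > min_prob].reset_index(drop=True)
    return frame, failures
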