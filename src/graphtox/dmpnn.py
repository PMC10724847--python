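"""Directed-edge message-passing encoder (D-MPNN) and classifier head.

Hidden states live on directed edges.  The state of edge v->w is initialized
from the source-atom and bond features; each update sums the states of edges
entering v while always excluding the reverse twin w->v, so a message never
immediately echoes back along the bond it came from.  The readout sums
incoming edge states per atom, maps them through a dense layer together with
the raw atom features, and sums over atoms to give a fixed-length molecule
embedding (sum aggregation preserves the disconnected-copy additivity used
in the tests; mean is available as an option).

Two call surfaces are provided: plain-NumPy single-graph operations
(`init_edge_states`, `message_step`, `readout`, `forward`) that define the
semantics and are checked against brute-force oracles, and autodiff-Tensor
batch operations (`encode_batch`) used for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .molgraph import FeatureVocab, MolGraph
from .nn import MLP, Linear, glorot

__all__ = [
    "DMPNNParams",
    "ClassifierHead",
    "GraphBatch",
    "init_edge_states",
    "message_step",
    "readout",
    "forward",
    "encode_batch",
]


@dataclass
class DMPNNParams:
    """Encoder parameters.

    W_input (d_atom + d_bond -> h) and W_message (h -> h) are pure linear
    maps; the readout layer (d_atom + h -> h) carries a bias.  ``depth`` is
    the number of message-passing steps T (T=0 uses the initial states
    directly).
    """

    W_input: ad.Tensor
    W_message: ad.Tensor
    readout_layer: Linear
    depth: int
    hidden: int
    aggregation: str = "sum"  # sum | mean

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        vocab: FeatureVocab,
        hidden: int = 300,
        depth: int = 3,
        aggregation: str = "sum",
    ) -> "DMPNNParams":
        if depth < 0:
            raise ValueError("depth must be >= 0")
        if aggregation not in ("sum", "mean"):
            raise ValueError("aggregation must be 'sum' or 'mean'")
        d_in = vocab.d_atom + vocab.d_bond
        return cls(
            W_input=ad.parameter(glorot(rng, d_in, hidden)),
            W_message=ad.parameter(glorot(rng, hidden, hidden)),
            readout_layer=Linear.init(rng, vocab.d_atom + hidden, hidden),
            depth=depth,
            hidden=hidden,
            aggregation=aggregation,
        )

    @property
    def parameters(self) -> list[ad.Tensor]:
        return [self.W_input, self.W_message] + self.readout_layer.parameters


@dataclass
class ClassifierHead:
    """Feed-forward head mapping an embedding to a logit; the predicted
    probability is the logistic of that logit and always lies in (0,1)."""

    mlp: MLP

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        n_in: int,
        hidden_sizes: tuple[int, ...] = (300,),
        dropout: float = 0.0,
    ) -> "ClassifierHead":
        return cls(MLP.init(rng, [n_in, *hidden_sizes, 1], dropout=dropout))

    def logits(self, x: ad.Tensor, rng: np.random.Generator | None = None) -> ad.Tensor:
        return self.mlp(x, rng=rng)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        out = ad.sigmoid(self.mlp(ad.constant(np.atleast_2d(x))))
        return out.data[:, 0]

    @property
    def parameters(self) -> list[ad.Tensor]:
        return self.mlp.parameters


# ---------------------------------------------------------------------------
# Plain-NumPy single-graph semantics


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def edge_inputs(g: MolGraph) -> np.ndarray:
    """Per directed edge v->w: concat(source atom features x_v, bond features e_vw)."""
    return np.concatenate([g.node_features[g.edge_src], g.edge_features], axis=1)


def init_edge_states(g: MolGraph, p: DMPNNParams) -> np.ndarray:
    """h0_vw = relu(W_input . concat(x_v, e_vw))."""
    x = edge_inputs(g)
    if x.shape[1] != p.W_input.data.shape[0]:
        raise ValueError(
            f"featurization width {x.shape[1]} does not match W_input rows {p.W_input.data.shape[0]}"
        )
    return _relu(x @ p.W_input.data)


def message_step(states: np.ndarray, g: MolGraph, h0: np.ndarray, p: DMPNNParams) -> np.ndarray:
    """One update: for edge v->w, m_vw sums states of edges k->v with k != w
    (the reverse edge w->v is always excluded); the new state is
    relu(h0_vw + W_message . m_vw)."""
    n_atoms = g.n_atoms
    atom_in = np.zeros((n_atoms, states.shape[1]))
    np.add.at(atom_in, g.edge_dst, states)
    m = atom_in[g.edge_src] - states[g.reverse_index]
    return _relu(h0 + m @ p.W_message.data)


def readout(states: np.ndarray, g: MolGraph, p: DMPNNParams) -> np.ndarray:
    """Aggregate edge states into a molecule embedding of length h."""
    atom_in = np.zeros((g.n_atoms, p.hidden))
    if g.n_dir_edges:
        np.add.at(atom_in, g.edge_dst, states)
    atom_h = _relu(
        np.concatenate([g.node_features, atom_in], axis=1) @ p.readout_layer.weight.data
        + p.readout_layer.bias.data
    )
    if p.aggregation == "mean":
        return atom_h.mean(axis=0)
    return atom_h.sum(axis=0)


def encode(g: MolGraph, p: DMPNNParams) -> np.ndarray:
    """Full encoder pass: T message steps then readout."""
    h = init_edge_states(g, p) if g.n_dir_edges else np.zeros((0, p.hidden))
    if g.n_dir_edges:
        h0 = h
        for _ in range(p.depth):
            h = message_step(h, g, h0, p)
    return readout(h, g, p)


def forward(g: MolGraph, p: DMPNNParams, head: ClassifierHead) -> float:
    """Probability in (0,1) for one molecule (evaluation mode, dropout off)."""
    return float(head.predict_proba(encode(g, p))[0])


# ---------------------------------------------------------------------------
# Batched autodiff path used for training


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs with per-atom molecule indices."""

    node_features: np.ndarray
    edge_input: np.ndarray  # (E, d_atom + d_bond)
    edge_src: np.ndarray
    edge_dst: np.ndarray
    reverse_index: np.ndarray
    mol_index: np.ndarray  # (N,) molecule id per atom
    n_mols: int
    atoms_per_mol: np.ndarray = field(default=None)

    @classmethod
    def from_graphs(cls, graphs: list[MolGraph]) -> "GraphBatch":
        if not graphs:
            raise ValueError("empty batch")
        node_feats, edge_ins, srcs, dsts, revs, mol_idx = [], [], [], [], [], []
        atom_off = edge_off = 0
        for i, g in enumerate(graphs):
            node_feats.append(g.node_features)
            edge_ins.append(edge_inputs(g))
            srcs.append(g.edge_src + atom_off)
            dsts.append(g.edge_dst + atom_off)
            revs.append(g.reverse_index + edge_off)
            mol_idx.append(np.full(g.n_atoms, i, dtype=np.intp))
            atom_off += g.n_atoms
            edge_off += g.n_dir_edges
        return cls(
            node_features=np.concatenate(node_feats),
            edge_input=np.concatenate(edge_ins) if edge_off else np.zeros((0, node_feats[0].shape[1] + graphs[0].edge_features.shape[1])),
            edge_src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.intp),
            edge_dst=np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.intp),
            reverse_index=np.concatenate(revs) if revs else np.zeros(0, dtype=np.intp),
            mol_index=np.concatenate(mol_idx),
            n_mols=len(graphs),
            atoms_per_mol=np.array([g.n_atoms for g in graphs], dtype=np.float64),
        )


def encode_batch(batch: GraphBatch, p: DMPNNParams) -> ad.Tensor:
    """Differentiable batched encoder: (n_mols, h) molecule embeddings."""
    n_atoms = batch.node_features.shape[0]
    nodes = ad.constant(batch.node_features)
    if batch.edge_input.shape[0] > 0:
        x = ad.constant(batch.edge_input)
        h0 = ad.relu(ad.matmul(x, p.W_input))
        h = h0
        for _ in range(p.depth):
            atom_in = ad.segment_sum(h, batch.edge_dst, n_atoms)
            m = ad.sub(ad.gather_rows(atom_in, batch.edge_src), ad.gather_rows(h, batch.reverse_index))
            h = ad.relu(ad.add(h0, ad.matmul(m, p.W_message)))
        atom_msg = ad.segment_sum(h, batch.edge_dst, n_atoms)
    else:
        atom_msg = ad.constant(np.zeros((n_atoms, p.hidden)))
    atom_h = ad.relu(p.readout_layer(ad.hstack(nodes, atom_msg)))
    emb = ad.segment_sum(atom_h, batch.mol_index, batch.n_mols)
    if p.aggregation == "mean":
        emb = ad.mul(emb, ad.constant(1.0 / batch.atoms_per_mol[:, None]))
    return emb
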