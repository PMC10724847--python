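"""Directed-edge molecular graph featurization.

Each bond contributes two directed edges (twins linked by ``reverse_index``);
atom and bond attributes are encoded as fixed-vocabulary one-hot blocks, each
with a trailing "unknown" slot, so the feature dimensionality is a pure
function of the :class:`FeatureVocab` and can be serialized with a model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .chemio import Atom, Bond, Molecule

logger = logging.getLogger(__name__)

__all__ = ["FeatureVocab", "MolGraph", "atom_feature_vector", "bond_feature_vector", "featurize"]

_warned_unknown: set[str] = set()


@dataclass(frozen=True)
class FeatureVocab:
    """Fixed featurization vocabulary; d_atom/d_bond derive from it."""

    elements: tuple[str, ...] = ("B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I")
    max_degree: int = 5
    charge_min: int = -2
    charge_max: int = 2
    bond_orders: tuple[str, ...] = ("single", "double", "triple", "aromatic")
    max_hydrogens: int = 4  # hydrogen count scaled to [0,1] by this divisor

    @property
    def d_atom(self) -> int:
        # element one-hot (+unknown), degree one-hot (+unknown),
        # charge one-hot (+unknown), aromatic flag, scaled H count
        return (
            (len(self.elements) + 1)
            + (self.max_degree + 2)
            + (self.charge_max - self.charge_min + 2)
            + 1
            + 1
        )

    @property
    def d_bond(self) -> int:
        return (len(self.bond_orders) + 1) + 1 + 1  # order one-hot (+unknown), in-ring, conjugated

    def to_json(self) -> str:
        return json.dumps(
            {
                "elements": list(self.elements),
                "max_degree": self.max_degree,
                "charge_min": self.charge_min,
                "charge_max": self.charge_max,
                "bond_orders": list(self.bond_orders),
                "max_hydrogens": self.max_hydrogens,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FeatureVocab":
        d = json.loads(s)
        return cls(
            elements=tuple(d["elements"]),
            max_degree=d["max_degree"],
            charge_min=d["charge_min"],
            charge_max=d["charge_max"],
            bond_orders=tuple(d["bond_orders"]),
            max_hydrogens=d["max_hydrogens"],
        )


def _one_hot(index: int, size: int) -> np.ndarray:
    """One-hot of length size+1; out-of-range values light the final slot."""
    v = np.zeros(size + 1)
    v[index if 0 <= index < size else size] = 1.0
    return v


def atom_feature_vector(atom: Atom, vocab: FeatureVocab) -> np.ndarray:
    """Concatenated one-hot element/degree/charge blocks + aromatic flag +
    scaled hydrogen count."""
    try:
        elem_idx = vocab.elements.index(atom.element)
    except ValueError:
        elem_idx = -1
        if atom.element not in _warned_unknown:
            _warned_unknown.add(atom.element)
            logger.info("element %r outside vocabulary; using unknown slot", atom.element)
    parts = [
        _one_hot(elem_idx, len(vocab.elements)),
        _one_hot(atom.degree, vocab.max_degree + 1),
        _one_hot(atom.formal_charge - vocab.charge_min, vocab.charge_max - vocab.charge_min + 1),
        np.array([1.0 if atom.aromatic else 0.0]),
        np.array([min(atom.n_hydrogens, vocab.max_hydrogens) / vocab.max_hydrogens]),
    ]
    return np.concatenate(parts)


def bond_feature_vector(bond: Bond, vocab: FeatureVocab) -> np.ndarray:
    """Bond-order one-hot + in-ring + conjugation flags; identical for the
    two directed twins of a bond (direction lives in the incidence maps)."""
    try:
        order_idx = vocab.bond_orders.index(bond.order)
    except ValueError:
        order_idx = -1
    parts = [
        _one_hot(order_idx, len(vocab.bond_orders)),
        np.array([1.0 if bond.in_ring else 0.0]),
        np.array([1.0 if bond.conjugated else 0.0]),
    ]
    return np.concatenate(parts)


@dataclass
class MolGraph:
    """Featurized directed-edge graph consumed by the message-passing encoder.

    Directed edge 2k points along bond k (atom_i -> atom_j); edge 2k+1 is its
    reverse twin.  ``incoming[v]`` lists the directed edges whose destination
    is atom v.
    """

    node_features: np.ndarray  # (n_atoms, d_atom)
    edge_features: np.ndarray  # (n_dir_edges, d_bond)
    edge_src: np.ndarray  # (n_dir_edges,)
    edge_dst: np.ndarray  # (n_dir_edges,)
    reverse_index: np.ndarray  # involution without fixed points
    incoming: list[list[int]] = field(repr=False)

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_dir_edges(self) -> int:
        return self.edge_features.shape[0]


def featurize(mol: Molecule, vocab: FeatureVocab | None = None) -> MolGraph:
    """Build the MolGraph for a molecule, preserving its atom order.

    Single-atom molecules yield zero edges; empty molecules are an error.
    """
    if vocab is None:
        vocab = FeatureVocab()
    if mol.n_atoms == 0:
        raise ValueError("cannot featurize an empty molecule")

    node_features = np.stack([atom_feature_vector(a, vocab) for a in mol.atoms])

    n_edges = 2 * mol.n_bonds
    edge_features = np.zeros((n_edges, vocab.d_bond))
    edge_src = np.zeros(n_edges, dtype=np.intp)
    edge_dst = np.zeros(n_edges, dtype=np.intp)
    reverse_index = np.zeros(n_edges, dtype=np.intp)
    incoming: list[list[int]] = [[] for _ in range(mol.n_atoms)]

    for k, bond in enumerate(mol.bonds):
        fv = bond_feature_vector(bond, vocab)
        e_fwd, e_rev = 2 * k, 2 * k + 1
        edge_features[e_fwd] = fv
        edge_features[e_rev] = fv
        edge_src[e_fwd], edge_dst[e_fwd] = bond.atom_i, bond.atom_j
        edge_src[e_rev], edge_dst[e_rev] = bond.atom_j, bond.atom_i
        reverse_index[e_fwd] = e_rev
        reverse_index[e_rev] = e_fwd
        incoming[bond.atom_j].append(e_fwd)
        incoming[bond.atom_i].append(e_rev)

    return MolGraph(
        node_features=node_features,
        edge_features=edge_features,
        edge_src=edge_src,
        edge_dst=edge_dst,
        reverse_index=reverse_index,
        incoming=incoming,
    )
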