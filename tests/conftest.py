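"""Shared fixtures: a diverse molecule panel and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from graphtox.chemio import Molecule, parse_smiles
from graphtox.dmpnn import DMPNNParams
from graphtox.molgraph import MolGraph

# Diverse panel: acyclic/aromatic/aliphatic rings, heteroatoms, charges,
# fused systems, small and mid-sized molecules.
FIXTURE_SMILES = [
    "C",                       # methane
    "O",                       # water
    "CCO",                     # ethanol
    "CC(=O)O",                 # acetic acid
    "c1ccccc1",                # benzene
    "Cc1ccccc1",               # toluene
    "Oc1ccccc1",               # phenol
    "Nc1ccccc1",               # aniline
    "O=[N+]([O-])c1ccccc1",    # nitrobenzene
    "c1ccncc1",                # pyridine
    "c1ccoc1",                 # furan
    "c1ccsc1",                 # thiophene
    "C1CCCCC1",                # cyclohexane
    "c1ccc2ccccc2c1",          # naphthalene
    "CC(=O)Oc1ccccc1C(=O)O",   # aspirin
    "CN1C(=O)N(C)c2ncn(C)c2C1=O",  # caffeine-like xanthine
]


@pytest.fixture(scope="session")
def fixture_molecules() -> list[Molecule]:
    return [parse_smiles(s) for s in FIXTURE_SMILES]


@pytest.fixture(scope="session")
def small_molecules(fixture_molecules) -> list[Molecule]:
    """Panel members with at most 10 heavy atoms (for brute-force oracles)."""
    return [m for m in fixture_molecules if m.n_atoms <= 10]


def random_smiles_rewrite(mol: Molecule, rng: np.random.Generator) -> str:
    """A randomized (non-canonical) SMILES writing of the same molecule,
    giving a random atom ordering on re-parse."""
    # RDKit's doRandom uses its own global RNG; seed it from ours.
    return Chem.MolToSmiles(
        mol._rdmol, canonical=False, doRandom=True
    )


def naive_edge_states(g: MolGraph, p: DMPNNParams, depth: int) -> np.ndarray:
    """Brute-force directed-edge message passing: explicit per-edge loops
    enumerating incoming edges and excluding the reverse twin.  Independent
    of the vectorized implementation."""
    relu = lambda a: np.maximum(a, 0.0)
    h0 = np.zeros((g.n_dir_edges, p.hidden))
    for e in range(g.n_dir_edges):
        x = np.concatenate([g.node_features[g.edge_src[e]], g.edge_features[e]])
        h0[e] = relu(x @ p.W_input.data)
    h = h0.copy()
    for _ in range(depth):
        new = np.zeros_like(h)
        for e in range(g.n_dir_edges):
            v = g.edge_src[e]
            m = np.zeros(p.hidden)
            for e2 in g.incoming[v]:
                if e2 != g.reverse_index[e]:
                    m = m + h[e2]
            new[e] = relu(h0[e] + m @ p.W_message.data)
        h = new
    return h


def naive_roc_auc(scores, labels) -> float:
    """All-pairs Mann-Whitney ROC-AUC (ties one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
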