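"""Synthetic chemical datasets with a planted substructure -> label rule.

Molecules are assembled from a pool of ring-scaffold cores (benzene,
pyridine, cyclohexane, naphthalene, furan, ...) by attaching 0-3 substituents
(methyl, hydroxyl, nitro, chloro, amino, carboxyl, ...) at ring carbons via
single bonds, so every generated SMILES is valid by construction.

The clean label combines two signal components, emulating how chemical
activity arises in practice: a local functional-group trigger (label 1 iff a
rule substructure, default the nitro group, is present) and scaffold-level
intrinsic activity (a per-seed subset of the cores is active regardless of
substitution; molecules sharing a scaffold tend to share target
relationships).  The scaffold component is what makes scaffold-held-out test
sets genuinely harder: an active core never seen in training is
unpredictable.  Set ``active_scaffold_fraction=0`` for a purely
substructure-determined label.  Clean labels are then flipped with a
configurable noise rate and masked with a missing-label rate; the clean
(pre-noise) labels are returned alongside so noise recovery is testable.

An unlabeled generator produces a pretraining pool with a much wider
molecular-weight range (long alkyl/ether chains permitted), emulating a
large structure inventory for autoencoder pretraining.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemio import DatasetTable

__all__ = ["SynthSpec", "CORES", "SUBSTITUENTS", "RULES", "generate", "generate_unlabeled"]

# Scaffold cores, in pool order.  Attachment sites are ring carbons that
# still carry a hydrogen, found at build time.
CORES: tuple[str, ...] = (
    "c1ccccc1",          # benzene
    "c1ccncc1",          # pyridine
    "C1CCCCC1",          # cyclohexane
    "c1ccc2ccccc2c1",    # naphthalene
    "c1ccoc1",           # furan
    "c1ccsc1",           # thiophene
    "C1CCCC1",           # cyclopentane
    "c1cncnc1",          # pyrimidine
    "C1CCNCC1",          # piperidine
    "c1ccc2[nH]ccc2c1",  # indole
)

# Substituent SMILES; atom 0 is the attachment point.
SUBSTITUENTS: tuple[str, ...] = (
    "C",             # methyl
    "CC",            # ethyl
    "O",             # hydroxyl
    "OC",            # methoxy
    "N",             # amino
    "Cl",            # chloro
    "F",             # fluoro
    "C(=O)O",        # carboxyl
    "[N+](=O)[O-]",  # nitro
)

_NITRO = "[N+](=O)[O-]"

# Label rules as SMARTS patterns.
RULES: dict[str, str] = {
    "nitro": "[N+](=O)[O-]",
    "hydroxyl": "[OX2H]",
    "halogen": "[F,Cl,Br,I]",
    "amino": "[NX3;H2]",
    "carboxyl": "C(=O)[OX2H1]",
}

# Extra long-chain substituents for the unlabeled pool (wider weight range).
_LONG_CHAINS: tuple[str, ...] = ("CCCC", "CCCCCC", "CCCCCCCC", "CCOCC", "CCCCCCCCCC")


@dataclass(frozen=True)
class SynthSpec:
    """Generator settings; defaults define the package's study conditions."""

    n: int = 2000
    scaffold_pool_size: int = 8
    substituent_pool: tuple[str, ...] = SUBSTITUENTS
    rule: str = "nitro"
    noise: float = 0.1
    missing_rate: float = 0.0
    endpoints: tuple[str, ...] = ("activity",)
    seed: int = 0
    rules: tuple[str, ...] | None = None
    p_rule_substituent: float = 0.3  # chance a substituent slot draws the nitro group
    active_scaffold_fraction: float = 0.25  # share of cores intrinsically active

    def __post_init__(self):
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("label noise must lie in [0, 0.5) so the signal stays learnable")
        if not 0.0 <= self.active_scaffold_fraction <= 1.0:
            raise ValueError("active_scaffold_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing-label rate must lie in [0, 1)")
        if not self.substituent_pool or not self.endpoints:
            raise ValueError("substituent pool and endpoint list must be non-empty")
        if not 1 <= self.scaffold_pool_size <= len(CORES):
            raise ValueError(
                f"scaffold_pool_size must be in [1, {len(CORES)}]; "
                f"requested {self.scaffold_pool_size}"
            )
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; options: {sorted(RULES)}")

    def endpoint_rules(self) -> dict[str, str]:
        if self.rules is not None:
            if len(self.rules) != len(self.endpoints):
                raise ValueError("rules must align with endpoints")
            return dict(zip(self.endpoints, self.rules))
        pool = [self.rule] + [r for r in RULES if r != self.rule]
        return {ep: pool[i % len(pool)] for i, ep in enumerate(self.endpoints)}


def _attach_sites(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1 and a.IsInRing()
    ]


def _assemble(core_smiles: str, subs: list[str], positions: list[int]) -> str:
    """Attach each substituent at a ring-carbon site by a single bond."""
    mol = Chem.RWMol(Chem.MolFromSmiles(core_smiles))
    for sub_smiles, pos in zip(subs, positions):
        sub = Chem.MolFromSmiles(sub_smiles)
        offset = mol.GetNumAtoms()
        combined = Chem.RWMol(Chem.CombineMols(mol, sub))
        combined.AddBond(pos, offset, Chem.BondType.SINGLE)
        mol = combined
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _core_weights(n_cores: int) -> np.ndarray:
    """Long-tailed (Zipf-like) scaffold frequencies: a few common cores and a
    tail of rare ones, as in real chemical inventories."""
    w = 1.0 / (np.arange(n_cores) + 1.0)
    return w / w.sum()


def _build_molecule(
    rng: np.random.Generator,
    cores: tuple[str, ...],
    sub_pool: tuple[str, ...],
    p_rule: float,
    max_subs: int = 3,
    core_weights: np.ndarray | None = None,
) -> tuple[str, int]:
    if core_weights is None:
        core_idx = int(rng.integers(len(cores)))
    else:
        core_idx = int(rng.choice(len(cores), p=core_weights))
    core = cores[core_idx]
    sites = _attach_sites(Chem.MolFromSmiles(core))
    k = int(rng.integers(0, min(max_subs, len(sites)) + 1))
    positions = list(rng.choice(len(sites), size=k, replace=False)) if k else []
    subs = []
    non_rule = [s for s in sub_pool if s != _NITRO] or list(sub_pool)
    for _ in range(k):
        if _NITRO in sub_pool and rng.random() < p_rule:
            subs.append(_NITRO)
        else:
            subs.append(non_rule[rng.integers(len(non_rule))])
    return _assemble(core, subs, [sites[p] for p in positions]), core_idx


def generate(spec: SynthSpec) -> tuple[DatasetTable, pd.DataFrame]:
    """Generate a labelled dataset plus the clean (pre-noise, pre-masking)
    ground-truth labels, deterministically per seed."""
    rng = np.random.default_rng(spec.seed)
    cores = CORES[: spec.scaffold_pool_size]
    rules = {ep: Chem.MolFromSmarts(RULES[r]) for ep, r in spec.endpoint_rules().items()}
    n_active = int(round(spec.active_scaffold_fraction * len(cores)))
    active_cores = set(rng.choice(len(cores), size=n_active, replace=False)) if n_active else set()

    weights = _core_weights(len(cores))
    smiles: list[str] = []
    core_ids = np.zeros(spec.n, dtype=int)
    clean = {ep: np.zeros(spec.n, dtype=int) for ep in spec.endpoints}
    for i in range(spec.n):
        smi, core_idx = _build_molecule(
            rng, cores, spec.substituent_pool, spec.p_rule_substituent, core_weights=weights
        )
        smiles.append(smi)
        core_ids[i] = core_idx
        mol = Chem.MolFromSmiles(smi)
        for ep, patt in rules.items():
            clean[ep][i] = int(mol.HasSubstructMatch(patt) or core_idx in active_cores)

    labels: list[dict[str, int | None]] = []
    for i in range(spec.n):
        row: dict[str, int | None] = {}
        for ep in spec.endpoints:
            y = int(clean[ep][i])
            if rng.random() < spec.noise:
                y = 1 - y
            row[ep] = None if rng.random() < spec.missing_rate else y
        labels.append(row)

    table = DatasetTable.from_records(smiles, labels, list(spec.endpoints))
    if table.skipped:  # construction guarantees validity; guard anyway
        raise RuntimeError(f"generator produced unparsable SMILES: {table.skipped}")
    truth = pd.DataFrame(
        {
            "smiles": smiles,
            "core": [cores[c] for c in core_ids],
            "core_active": [int(c in active_cores) for c in core_ids],
            **{ep: clean[ep] for ep in spec.endpoints},
        }
    )
    return table, truth


def generate_unlabeled(n: int, seed: int = 0) -> list[str]:
    """Unlabeled SMILES pool for pretraining: ring systems with substituents
    mixed with alkyl/ether chains of widely varying length, giving a much
    broader molecular-weight range than the labelled generator."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pool = SUBSTITUENTS + _LONG_CHAINS
    out: list[str] = []
    for _ in range(n):
        if rng.random() < 0.4:
            out.append("C" * int(rng.integers(1, 25)))
        else:
            out.append(_build_molecule(rng, CORES, pool, p_rule=0.15)[0])
    return out
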