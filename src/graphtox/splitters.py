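"""Train/test partitioning: random, Bemis-Murcko scaffold, molecular-weight
strategies, and k-fold cross-validation assignment.

Scaffold splitting assigns whole scaffold groups to one side so no scaffold
appears in both train and test; weight splitting holds out a contiguous
weight range (train takes the lighter molecules by default), so the maximum
training weight never exceeds the minimum test weight.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .chemio import Molecule, molecular_weight, murcko_scaffold

__all__ = ["SplitSpec", "SplitResult", "UnsplittableError", "random_split", "scaffold_split", "weight_split", "kfold_assign", "make_split"]


class UnsplittableError(ValueError):
    """Raised when a strategy cannot produce two non-empty sides."""


@dataclass(frozen=True)
class SplitSpec:
    strategy: str = "random"  # random | scaffold | weight
    train_fraction: float = 0.8
    seed: int = 0
    weight_direction: str = "light_to_heavy"  # or heavy_to_light

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly inside (0,1)")
        if self.strategy not in ("random", "scaffold", "weight"):
            raise ValueError(f"unknown split strategy {self.strategy!r}")
        if self.weight_direction not in ("light_to_heavy", "heavy_to_light"):
            raise ValueError(f"unknown weight_direction {self.weight_direction!r}")


@dataclass(frozen=True)
class SplitResult:
    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]

    def __post_init__(self):
        train, test = set(self.train_idx), set(self.test_idx)
        if not self.train_idx or not self.test_idx:
            raise UnsplittableError("both split sides must be non-empty")
        if train & test:
            raise ValueError("train and test indices overlap")

    @property
    def n(self) -> int:
        return len(self.train_idx) + len(self.test_idx)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _target_train_size(n: int, fraction: float) -> int:
    size = _round_half_up(n * fraction)
    if size < 1 or size > n - 1:
        raise UnsplittableError(
            f"train fraction {fraction} on n={n} leaves an empty side"
        )
    return size


def random_split(n: int, spec: SplitSpec) -> SplitResult:
    """Seeded uniform shuffle; |train| = round(n * fraction), half-up."""
    if n < 2:
        raise UnsplittableError("need at least 2 records to split")
    size = _target_train_size(n, spec.train_fraction)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    return SplitResult(tuple(int(i) for i in perm[:size]), tuple(int(i) for i in perm[size:]))


def scaffold_split(mols: list[Molecule], spec: SplitSpec) -> SplitResult:
    """Group molecules by Murcko scaffold key and fill the train side greedily.

    Groups are taken in descending size (ties by lexicographic scaffold key)
    until the train side reaches round(n * fraction); remaining groups form
    the test side, so no scaffold key spans both sides.  Acyclic molecules
    (empty scaffold) form one ordinary group.  Requires >= 2 distinct
    scaffolds; otherwise raises, directing the user to a random split.
    """
    n = len(mols)
    if n < 2:
        raise UnsplittableError("need at least 2 molecules to split")
    groups: dict[str, list[int]] = defaultdict(list)
    for i, mol in enumerate(mols):
        groups[murcko_scaffold(mol)].append(i)
    if len(groups) < 2:
        raise UnsplittableError(
            "only one scaffold group present; scaffold splitting is impossible "
            "(use the random strategy instead)"
        )
    target = _target_train_size(n, spec.train_fraction)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    train: list[int] = []
    test: list[int] = []
    for _, idxs in ordered:
        if len(train) < target:
            train.extend(idxs)
        else:
            test.extend(idxs)
    if not test:
        # the greedy fill consumed every group; hold out the last one
        last = ordered[-1][1]
        train = [i for i in train if i not in set(last)]
        test = list(last)
    return SplitResult(tuple(train), tuple(test))


def weight_split(mols: list[Molecule], spec: SplitSpec) -> SplitResult:
    """Sort by molecular weight (ties by canonical SMILES) and cut at
    round(n * fraction); seed-independent and order-independent.

    Default direction trains on the lighter molecules and tests on the
    heavier remainder, so max(train weight) <= min(test weight).
    """
    n = len(mols)
    if n < 2:
        raise UnsplittableError("need at least 2 molecules to split")
    size = _target_train_size(n, spec.train_fraction)
    order = sorted(range(n), key=lambda i: (molecular_weight(mols[i]), mols[i].canonical_smiles))
    if spec.weight_direction == "heavy_to_light":
        order = order[::-1]
    return SplitResult(tuple(order[:size]), tuple(order[size:]))


def make_split(mols: list[Molecule], spec: SplitSpec) -> SplitResult:
    """Dispatch on spec.strategy."""
    if spec.strategy == "random":
        return random_split(len(mols), spec)
    if spec.strategy == "scaffold":
        return scaffold_split(mols, spec)
    return weight_split(mols, spec)


def kfold_assign(n: int, k: int = 5, seed: int = 0) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Seeded k-fold partition: every index lands in exactly one validation
    fold; folds differ in size by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} records")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        val = folds[i]
        train = np.concatenate([folds[j] for j in range(k) if j != i])
        out.append((tuple(int(x) for x in train), tuple(int(x) for x in val)))
    return out
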