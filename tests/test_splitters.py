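"""Partition contracts for random, scaffold and weight splitting and k-fold
assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graphtox.chemio import molecular_weight, murcko_scaffold, parse_smiles
from graphtox.splitters import (
    SplitSpec,
    UnsplittableError,
    kfold_assign,
    random_split,
    scaffold_split,
    weight_split,
)


class TestRandomSplit:
    def test_rounding_rule(self):
        res = random_split(10, SplitSpec("random", 0.8, seed=0))
        assert len(res.train_idx) == 8 and len(res.test_idx) == 2

    def test_half_up_rounding(self):
        res = random_split(10, SplitSpec("random", 0.55, seed=0))
        assert len(res.train_idx) == 6  # round(5.5) half-up

    def test_same_seed_reproduces(self):
        spec = SplitSpec("random", 0.7, seed=123)
        assert random_split(20, spec) == random_split(20, spec)

    @settings(derandomize=True, max_examples=200)
    @given(n=st.integers(2, 200), seed=st.integers(0, 2**31 - 1), frac=st.floats(0.1, 0.9))
    def test_partition_contract(self, n, seed, frac):
        import math

        try:
            res = random_split(n, SplitSpec("random", frac, seed=seed))
        except UnsplittableError:
            size = math.floor(n * frac + 0.5)
            assert size < 1 or size > n - 1
            return
        assert set(res.train_idx) | set(res.test_idx) == set(range(n))
        assert not set(res.train_idx) & set(res.test_idx)

    def test_empty_side_errors(self):
        with pytest.raises(UnsplittableError):
            random_split(2, SplitSpec("random", 0.01, seed=0))


def _mols(smiles):
    return [parse_smiles(s) for s in smiles]


class TestScaffoldSplit:
    def test_greedy_fill_groups_8_2(self):
        mols = _mols(["Cc1ccccc1"] * 8 + ["Cc1ccncc1"] * 2)
        res = scaffold_split(mols, SplitSpec("scaffold", 0.8, seed=0))
        assert sorted(res.train_idx) == list(range(8))
        assert sorted(res.test_idx) == [8, 9]

    def test_greedy_fill_stops_once_target_reached(self):
        # groups {5,3,2}, fraction 0.5: first group alone reaches the target
        mols = _mols(["Cc1ccccc1"] * 5 + ["Cc1ccncc1"] * 3 + ["CC1CCCCC1"] * 2)
        res = scaffold_split(mols, SplitSpec("scaffold", 0.5, seed=0))
        assert sorted(res.train_idx) == list(range(5))
        assert sorted(res.test_idx) == list(range(5, 10))

    def test_no_scaffold_overlap(self, fixture_molecules):
        mols = fixture_molecules * 3
        res = scaffold_split(mols, SplitSpec("scaffold", 0.6, seed=0))
        train_keys = {murcko_scaffold(mols[i]) for i in res.train_idx}
        test_keys = {murcko_scaffold(mols[i]) for i in res.test_idx}
        assert not train_keys & test_keys

    def test_single_scaffold_group_unsplittable(self):
        with pytest.raises(UnsplittableError, match="random"):
            scaffold_split(_mols(["c1ccccc1", "Cc1ccccc1", "CCc1ccccc1"]), SplitSpec("scaffold", 0.5))

    def test_acyclic_molecules_form_one_group(self):
        mols = _mols(["CCO", "CCC", "CCN", "c1ccccc1", "Cc1ccccc1"])
        res = scaffold_split(mols, SplitSpec("scaffold", 0.6, seed=0))
        acyclic = {0, 1, 2}
        for side in (set(res.train_idx), set(res.test_idx)):
            assert acyclic <= side or not acyclic & side

    def test_achieved_fraction_within_granularity_bound(self, fixture_molecules):
        mols = fixture_molecules * 4
        n = len(mols)
        groups = {}
        for m in mols:
            groups.setdefault(murcko_scaffold(m), []).append(m)
        largest = max(len(v) for v in groups.values())
        for frac in (0.5, 0.7, 0.8):
            res = scaffold_split(mols, SplitSpec("scaffold", frac, seed=0))
            assert abs(len(res.train_idx) / n - frac) <= largest / n


class TestWeightSplit:
    def test_lightest_in_train(self):
        mols = _mols(["C", "O", "CCO", "c1ccccc1"])  # 16, 18, 46, 78 Da
        res = weight_split(mols, SplitSpec("weight", 0.5))
        assert sorted(res.train_idx) == [0, 1]
        assert sorted(res.test_idx) == [2, 3]

    def test_defining_property(self, fixture_molecules):
        res = weight_split(fixture_molecules, SplitSpec("weight", 0.6))
        max_train = max(molecular_weight(fixture_molecules[i]) for i in res.train_idx)
        min_test = min(molecular_weight(fixture_molecules[i]) for i in res.test_idx)
        assert max_train <= min_test

    def test_input_order_independent(self, fixture_molecules):
        spec = SplitSpec("weight", 0.6)
        res = weight_split(fixture_molecules, spec)
        perm = list(reversed(range(len(fixture_molecules))))
        res_perm = weight_split([fixture_molecules[i] for i in perm], spec)
        # map permuted indices back to original identities
        train_mols = {fixture_molecules[perm[i]].canonical_smiles for i in res_perm.train_idx}
        assert train_mols == {fixture_molecules[i].canonical_smiles for i in res.train_idx}

    def test_heavy_to_light_direction_flag(self):
        mols = _mols(["C", "O", "CCO", "c1ccccc1"])
        res = weight_split(mols, SplitSpec("weight", 0.5, weight_direction="heavy_to_light"))
        assert sorted(res.train_idx) == [2, 3]


class TestKFold:
    def test_five_folds_of_two(self):
        folds = kfold_assign(10, 5, seed=0)
        assert len(folds) == 5
        assert all(len(val) == 2 for _, val in folds)

    @settings(derandomize=True, max_examples=100)
    @given(n=st.integers(5, 100), k=st.integers(2, 5), seed=st.integers(0, 10_000))
    def test_validation_folds_partition_indices(self, n, k, seed):
        if n < k:
            return
        folds = kfold_assign(n, k, seed=seed)
        all_val = [i for _, val in folds for i in val]
        assert sorted(all_val) == list(range(n))
        sizes = {len(val) for _, val in folds}
        assert max(sizes) - min(sizes) <= 1
        for train, val in folds:
            assert sorted(train + val) == list(range(n))

    def test_same_seed_identical(self):
        assert kfold_assign(17, 4, seed=3) == kfold_assign(17, 4, seed=3)

    def test_too_few_records_errors(self):
        with pytest.raises(ValueError):
            kfold_assign(3, 5, seed=0)


class TestSpecValidation:
    def test_fraction_must_be_interior(self):
        for frac in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                SplitSpec("random", frac)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec("temporal", 0.8)

    def test_repeated_invocation_equality(self, fixture_molecules):
        for strat in ("random", "scaffold", "weight"):
            spec = SplitSpec(strat, 0.6, seed=7)
            if strat == "random":
                assert random_split(len(fixture_molecules), spec) == random_split(len(fixture_molecules), spec)
            elif strat == "scaffold":
                assert scaffold_split(fixture_molecules, spec) == scaffold_split(fixture_molecules, spec)
            else:
                assert weight_split(fixture_molecules, spec) == weight_split(fixture_molecules, spec)
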