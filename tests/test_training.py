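"""Metrics, cross-validation orchestration, bundles and ranked prediction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import graphtox as gt
from graphtox.training import (
    TrainConfig,
    UndefinedMetricError,
    binary_accuracy,
    cross_validate,
    evaluate_holdout,
    predict_rank,
    roc_auc,
)
from conftest import naive_roc_auc


class TestBinaryAccuracy:
    @pytest.mark.parametrize(
        "probs,labels,expected",
        [
            ((0.9, 0.1), (1, 0), 1.0),
            ((0.9, 0.1), (0, 1), 0.0),
            ((0.6, 0.6), (1, 0), 0.5),
        ],
    )
    def test_examples(self, probs, labels, expected):
        assert binary_accuracy(probs, labels, 0.5) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            binary_accuracy([0.5], [1, 0])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_tie_counts_half(self):
        assert roc_auc([0.8, 0.8], [1, 0]) == 0.5

    def test_hand_computed_example(self):
        # positives {0.9, 0.2}, negatives {0.4, 0.7}: concordant pairs are
        # (0.9,0.4) and (0.9,0.7) only -> 2 of 4 pairs -> 0.5
        scores, labels = [0.9, 0.4, 0.7, 0.2], [1, 0, 0, 1]
        assert naive_roc_auc(scores, labels) == 0.5
        assert roc_auc(scores, labels) == 0.5

    def test_single_class_is_undefined_not_zero(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(2, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            assert roc_auc(scores, labels) == pytest.approx(
                naive_roc_auc(scores, labels), abs=1e-12
            )

    def test_cross_check_against_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.random(n)
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


@pytest.fixture(scope="module")
def tiny_table():
    table, _ = gt.generate(gt.SynthSpec(n=80, noise=0.0, seed=5, scaffold_pool_size=5))
    return table


TINY_CFG = TrainConfig(
    model="gnn", endpoint="activity", k=3, epochs=2, batch_size=32,
    hidden=12, depth=1, head_hidden=(12,), seed=0,
)


class TestCrossValidate:
    def test_shapes_and_ranges(self, tiny_table):
        res = cross_validate(tiny_table, TINY_CFG)
        assert list(res.folds["fold"]) == [0, 1, 2]
        assert ((res.folds[["accuracy", "roc_auc"]] >= 0) & (res.folds[["accuracy", "roc_auc"]] <= 1)).all().all()
        assert len(res.bundles) == 3
        assert res.best_fold == int(res.folds["roc_auc"].idxmax())

    def test_determinism(self, tiny_table):
        a = cross_validate(tiny_table, TINY_CFG)
        b = cross_validate(tiny_table, TINY_CFG)
        pd.testing.assert_frame_equal(a.folds, b.folds)

    def test_single_class_endpoint_errors_with_name(self, tiny_table):
        rows = tiny_table.to_frame()
        rows["activity"] = 0
        bad = gt.DatasetTable.from_records(
            list(rows["smiles"]), [{"activity": 0}] * len(rows), ["activity"]
        )
        with pytest.raises(ValueError, match="activity"):
            cross_validate(bad, TINY_CFG)

    def test_unknown_endpoint_errors(self, tiny_table):
        with pytest.raises(ValueError):
            cross_validate(tiny_table, TrainConfig(endpoint="nope", k=3))

    def test_ae_path_runs(self, tiny_table):
        cfg = TrainConfig(
            model="ae+ffnn", endpoint="activity", k=3, epochs=3, batch_size=32,
            n_bits=256, ae_hidden=(64,), latent_dim=16, ae_epochs=2, seed=0,
            head_hidden=(16,),
        )
        res = cross_validate(tiny_table, cfg)
        assert len(res.bundles) == 3
        assert res.folds["roc_auc"].between(0, 1).all()


@pytest.fixture(scope="module")
def fitted(tiny_table):
    return cross_validate(tiny_table, TINY_CFG).best_bundle


class TestBundlesAndPrediction:

    def test_save_load_round_trip(self, fitted, tiny_table, tmp_path):
        path = tmp_path / "model.bundle"
        fitted.save(path)
        loaded = gt.ModelBundle.load(path)
        mols = tiny_table.molecules[:10]
        assert np.allclose(
            fitted.predict_proba_molecules(mols), loaded.predict_proba_molecules(mols)
        )

    def test_predict_rank_ordering_and_failures(self, fitted):
        smiles = ["CCO", "c1ccccc1", "NOT_SMILES", "CCO"]
        frame, failures = predict_rank(fitted, smiles)
        assert failures == ["NOT_SMILES"]
        assert len(frame) == 3
        probs = frame["probability"].to_numpy()
        assert np.all(np.diff(probs) <= 0)
        dup = frame[frame["smiles"] == "CCO"]["probability"]
        assert dup.nunique() == 1  # duplicate inputs share a probability

    def test_min_prob_filter(self, fitted):
        frame, _ = predict_rank(fitted, ["CCO", "c1ccccc1"], min_prob=0.8)
        assert (frame["probability"] > 0.8).all()

    def test_evaluate_holdout_masks_missing(self, fitted, tiny_table):
        rec = evaluate_holdout(fitted, tiny_table, "activity")
        assert rec.n == len(tiny_table)
        assert 0 <= rec.accuracy <= 1 and 0 <= rec.roc_auc <= 1

    def test_evaluate_holdout_empty_labels_error(self, fitted):
        empty = gt.DatasetTable.from_records(["CCO", "c1ccccc1"], [{"activity": None}] * 2, ["activity"])
        with pytest.raises(ValueError):
            evaluate_holdout(fitted, empty, "activity")

    def test_train_overfits_relative_to_scaffold_holdout(self, tiny_table):
        """A model evaluated on its own training data scores at least as
        well as on a scaffold-held-out test set (directional, one seed pair
        averaged over folds is enough at this size)."""
        from graphtox.splitters import SplitSpec, scaffold_split

        split = scaffold_split(tiny_table.molecules, SplitSpec("scaffold", 0.7, seed=0))
        train = tiny_table.subset(split.train_idx)
        test = tiny_table.subset(split.test_idx)
        res = gt.GraphClassifier(train, "activity", hidden=16, depth=2, head_hidden=(16,)).fit(
            epochs=30, batch_size=32, seed=0
        )
        on_train = res.evaluate(train).roc_auc
        on_test = res.evaluate(test).roc_auc
        assert on_train >= on_test - 0.05
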