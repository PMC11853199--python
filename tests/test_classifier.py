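import numpy as np
import pandas as pd
import pytest

from lungscreen.classifier import (
    ModelConfig,
    balance_classes,
    evaluate_accuracy,
    hidden_node_sweep,
    load_model,
    predict,
    predict_proba,
    save_model,
    split_dataset,
    train,
)
from lungscreen.errors import ContractError

LABELS = ["healthy", "pneumonia", "copd", "other"]


def _toy_table(seed=0, n_per_class=4, noise=0.05):
    """16 points at the corners of a square: linearly separable 4-class set."""
    rng = np.random.default_rng(seed)
    corners = {"healthy": (0, 0), "pneumonia": (0, 1), "copd": (1, 0), "other": (1, 1)}
    rows = []
    for label, (x, y) in corners.items():
        for _ in range(n_per_class):
            rows.append(
                {"f1": x + rng.normal(0, noise), "f2": y + rng.normal(0, noise), "label": label}
            )
    return pd.DataFrame(rows)


def _balanced_table(counts, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for label, n in zip(LABELS, counts):
        for _ in range(n):
            rows.append({"f1": rng.normal(), "f2": rng.normal(), "label": label})
    return pd.DataFrame(rows)


TOY_CONFIG = ModelConfig(
    n_hidden=32,
    max_epochs=400,
    dropout_rate=0.0,
    l2_penalty=1e-6,
    early_stopping_patience=None,
    seed=0,
)


class TestSplitDataset:
    def test_stratified_80_20(self):
        table = _balanced_table([25, 25, 25, 25])
        train_tbl, test_tbl = split_dataset(table, test_fraction=0.2, seed=0)
        assert len(train_tbl) == 80 and len(test_tbl) == 20
        assert (train_tbl["label"].value_counts() == 20).all()
        assert (test_tbl["label"].value_counts() == 5).all()

    def test_deterministic_given_seed(self):
        table = _balanced_table([10, 10, 10, 10])
        a = split_dataset(table, seed=3)
        b = split_dataset(table, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_disjoint_and_exhaustive(self):
        table = _balanced_table([10, 10, 10, 10]).reset_index(drop=True)
        table["row_id"] = range(len(table))
        train_tbl, test_tbl = split_dataset(table, seed=1)
        train_ids, test_ids = set(train_tbl["row_id"]), set(test_tbl["row_id"])
        assert train_ids.isdisjoint(test_ids)
        assert train_ids | test_ids == set(range(len(table)))

    def test_class_with_one_row_rejected(self):
        with pytest.raises(ContractError):
            split_dataset(_balanced_table([1, 5, 5, 5]))


class TestBalanceClasses:
    def test_oversamples_to_majority(self):
        table = _balanced_table([50, 5, 10, 20])
        balanced = balance_classes(table, seed=0)
        assert (balanced["label"].value_counts() == 50).all()

    def test_already_balanced_unchanged(self):
        table = _balanced_table([10, 10, 10, 10])
        balanced = balance_classes(table, seed=0)
        a = table.sort_values(["label", "f1"]).reset_index(drop=True)
        b = balanced.sort_values(["label", "f1"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_seeded_reproducible(self):
        table = _balanced_table([20, 3, 7, 11])
        a = balance_classes(table, seed=5)
        b = balance_classes(table, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestTrain:
    def test_separable_toy_set_reaches_full_training_accuracy(self):
        """Linear separability implies attainable zero training error."""
        for seed in range(5):
            table = _toy_table(seed=seed)
            model = train(table, ModelConfig(**{**TOY_CONFIG.__dict__, "seed": seed}),
                          feature_names=["f1", "f2"])
            assert evaluate_accuracy(model, table) == 1.0

    def test_seeded_determinism_identical_weights(self):
        table = _toy_table()
        config = ModelConfig(n_hidden=16, max_epochs=30, seed=7)
        a = train(table, config, feature_names=["f1", "f2"])
        b = train(table, config, feature_names=["f1", "f2"])
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.w2, b.w2)
        assert np.array_equal(a.b1, b.b1) and np.array_equal(a.b2, b.b2)

    def test_huge_l2_penalty_crushes_weights(self):
        table = _toy_table()
        config = ModelConfig(
            n_hidden=8, max_epochs=800, batch_size=4, l2_penalty=1e6,
            dropout_rate=0.0, early_stopping_patience=None, seed=0,
        )
        model = train(table, config, feature_names=["f1", "f2"])
        assert np.max(np.abs(model.w1)) < 1e-2
        assert np.max(np.abs(model.w2)) < 1e-2

    def test_non_finite_features_rejected(self):
        table = _toy_table()
        table.loc[0, "f1"] = np.nan
        with pytest.raises(ContractError):
            train(table, TOY_CONFIG, feature_names=["f1", "f2"])

    def test_four_class_output_width(self):
        model = train(_toy_table(), TOY_CONFIG, feature_names=["f1", "f2"])
        assert model.w2.shape[1] == 4
        assert model.class_order == ("healthy", "pneumonia", "copd", "other")


@pytest.fixture(scope="module")
def model():
    return train(_toy_table(), TOY_CONFIG, feature_names=["f1", "f2"])


class TestPredictProba:
    def test_probabilities_sum_to_one(self, model):
        rng = np.random.default_rng(0)
        probs = predict_proba(model, rng.normal(size=(50, 2)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_pure_function_on_duplicate_rows(self, model):
        x = np.array([[0.3, 0.7], [0.3, 0.7]])
        probs = predict_proba(model, x)
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_argmax_matches_labels_on_toy_set(self, model):
        table = _toy_table()
        predicted = predict(model, table[["f1", "f2"]].to_numpy())
        assert np.mean(predicted == table["label"].to_numpy()) >= 15 / 16

    def test_width_mismatch_rejected(self, model):
        with pytest.raises(ContractError):
            predict_proba(model, np.zeros(3))

    def test_class_order_permutation_permutes_probabilities(self, model):
        """Permuting the output layer and class order together leaves the
        per-class probabilities attached to their labels."""
        perm = [2, 0, 3, 1]
        permuted = load_model_like(model, perm)
        x = np.array([0.2, 0.9])
        base = dict(zip(model.class_order, predict_proba(model, x)))
        new = dict(zip(permuted.class_order, predict_proba(permuted, x)))
        for label in model.class_order:
            assert np.isclose(base[label], new[label])


def load_model_like(model, perm):
    from dataclasses import replace

    return replace(
        model,
        w2=model.w2[:, perm],
        b2=model.b2[perm],
        class_order=tuple(model.class_order[i] for i in perm),
    )


@pytest.fixture(scope="module")
def sweep(small_feature_table):
    config = ModelConfig(
        max_epochs=60, early_stopping_patience=None, dropout_rate=0.0, seed=0
    )
    return hidden_node_sweep(
        small_feature_table, node_counts=[8, 32, 64], base_config=config, split_seed=0
    )


class TestHiddenNodeSweep:
    def test_one_row_per_count(self, sweep):
        results, _ = sweep
        assert [r.n_hidden for r in results] == [8, 32, 64]

    def test_accuracies_in_unit_interval(self, sweep):
        results, _ = sweep
        for r in results:
            assert 0.0 <= r.train_accuracy <= 1.0
            assert 0.0 <= r.test_accuracy <= 1.0

    def test_selection_rule_smallest_gap_among_top(self, sweep):
        """Recompute the documented rule independently from the rows."""
        results, selected = sweep
        best = max(r.test_accuracy for r in results)
        candidates = [r for r in results if r.test_accuracy >= best - 0.01]
        expected = min(
            candidates, key=lambda r: (abs(r.train_accuracy - r.test_accuracy), r.n_hidden)
        ).n_hidden
        assert selected == expected

    def test_empty_counts_rejected(self, small_feature_table):
        with pytest.raises(ContractError):
            hidden_node_sweep(small_feature_table, node_counts=[])


class TestModelArchive:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = train(_toy_table(), TOY_CONFIG, feature_names=["f1", "f2"])
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        x = np.random.default_rng(0).normal(size=(10, 2))
        np.testing.assert_allclose(predict_proba(back, x), predict_proba(model, x))
        assert back.feature_names == model.feature_names
        assert back.class_order == model.class_order

    def test_unknown_schema_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"schema_version": 99}')
        with pytest.raises(ContractError):
            load_model(path)
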