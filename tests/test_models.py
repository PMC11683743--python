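"""Classifier back-ends, CRF marginal correctness, and feature selection."""

import itertools

import numpy as np
import pytest

from patchsleep.config import ModelSpec
from patchsleep.models import (
    apply_threshold,
    backward_greedy_selection,
    build_sequences,
    predict_sleep_probability,
    train_classifier,
)
from patchsleep.models import selection as selection_mod
from patchsleep.models.crf import _node_potentials, marginals

from conftest import make_synthetic_table


def brute_force_marginals(node: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Posterior marginals by explicit enumeration of every label sequence."""
    T = node.shape[0]
    logw = []
    labels = list(itertools.product([0, 1], repeat=T))
    for lab in labels:
        s = sum(node[t, lab[t]] for t in range(T))
        s += sum(A[lab[t - 1], lab[t]] for t in range(1, T))
        logw.append(s)
    logw = np.array(logw)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    out = np.zeros((T, 2))
    for weight, lab in zip(w, labels):
        for t, y in enumerate(lab):
            out[t, y] += weight
    return out


class TestCrfMarginals:
    @pytest.mark.parametrize("T", [1, 2, 5, 12])
    def test_forward_backward_matches_enumeration(self, T):
        rng = np.random.default_rng(T)
        node = rng.normal(scale=1.5, size=(T, 2))
        A = rng.normal(scale=1.0, size=(2, 2))
        fb = marginals(node, A)
        brute = brute_force_marginals(node, A)
        assert np.abs(fb - brute).max() <= 1e-8

    def test_marginals_normalize(self):
        rng = np.random.default_rng(0)
        node = rng.normal(size=(30, 2))
        A = rng.normal(size=(2, 2))
        assert np.allclose(marginals(node, A).sum(axis=1), 1.0, atol=1e-9)

    def test_fitted_crf_marginals_match_enumeration(self):
        # end-to-end: learned weights, short night, enumeration oracle
        table = make_synthetic_table(n_participants=6, windows_per_night=10, seed=4)
        spec = ModelSpec(kind="crf", seed=0)
        cols = ["informative", "noise_0", "noise_1", "noise_2"]
        model = train_classifier(spec, table, cols)
        seq = build_sequences(table[table["participant"] == "S00"], cols)[0]
        std = model._standardized(seq)
        X1 = np.hstack([std.X, np.ones((std.X.shape[0], 1))])
        node = _node_potentials(X1, model.W)
        assert np.abs(
            marginals(node, model.A) - brute_force_marginals(node, model.A)
        ).max() <= 1e-8


class TestThreshold:
    def test_zero_threshold_labels_everything_sleep(self):
        p = np.array([0.0, 0.2, 0.9])
        assert apply_threshold(p, 0.0).tolist() == [1, 1, 1]

    def test_unit_threshold_requires_certainty(self):
        p = np.array([1.0, 0.999])
        assert apply_threshold(p, 1.0).tolist() == [1, 0]
        with pytest.raises(ValueError):
            apply_threshold(p, 1.5)

    def test_rule_is_geq(self):
        p = np.array([0.8, 0.6, 0.4])
        assert apply_threshold(p, 0.75).tolist() == [1, 0, 0]
        assert apply_threshold(np.array([0.75]), 0.75).tolist() == [1]


@pytest.mark.parametrize("kind", ["gbm", "crf", "lstm"])
class TestBackends:
    def _spec(self, kind, seed=0):
        hp = {"hidden": 8} if kind == "lstm" else {}
        return ModelSpec(kind=kind, hyperparameters=hp, seed=seed)

    def test_separable_features_fit_to_high_f1(self, kind):
        table = make_synthetic_table(n_participants=6, effect=6.0, seed=1)
        cols = ["informative", "noise_0", "noise_1", "noise_2"]
        model = train_classifier(self._spec(kind), table, cols)
        preds = predict_sleep_probability(model, table)
        yhat = apply_threshold(preds["p_sleep"].to_numpy(), 0.5)
        y = preds["label"].to_numpy()
        tp = np.sum((y == 1) & (yhat == 1))
        f1 = 2 * tp / (2 * tp + np.sum(y != yhat))
        assert f1 >= 0.99

    def test_same_data_and_seed_reproduce_predictions(self, kind):
        table = make_synthetic_table(n_participants=5, seed=2)
        cols = ["informative", "noise_0", "noise_1", "noise_2"]
        p1 = predict_sleep_probability(
            train_classifier(self._spec(kind, 3), table, cols), table
        )["p_sleep"]
        p2 = predict_sleep_probability(
            train_classifier(self._spec(kind, 3), table, cols), table
        )["p_sleep"]
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())

    def test_single_window_night_predicts(self, kind):
        table = make_synthetic_table(n_participants=6, seed=5)
        cols = ["informative", "noise_0", "noise_1", "noise_2"]
        model = train_classifier(self._spec(kind), table, cols)
        one = table[(table["participant"] == "S00")].head(1)
        preds = predict_sleep_probability(model, one)
        assert len(preds) == 1
        assert 0.0 <= preds["p_sleep"].iloc[0] <= 1.0

    def test_schema_mismatch_names_missing_columns(self, kind):
        table = make_synthetic_table(n_participants=5, seed=6)
        cols = ["informative", "noise_0", "noise_1", "noise_2"]
        model = train_classifier(self._spec(kind), table, cols)
        with pytest.raises(ValueError, match="noise_2"):
            predict_sleep_probability(model, table.drop(columns=["noise_2"]))


class TestTrainingHygiene:
    def test_standardization_uses_training_windows_only(self):
        table = make_synthetic_table(n_participants=6, seed=7)
        cols = ["informative", "noise_0"]
        train = table[table["participant"] != "S05"]
        model = train_classifier(ModelSpec(kind="gbm"), train, cols)
        np.testing.assert_allclose(
            model.scaler.mean, train[cols].to_numpy().mean(axis=0)
        )

    def test_single_class_labels_rejected(self):
        table = make_synthetic_table(n_participants=4, seed=8)
        table["label"] = 1
        with pytest.raises(ValueError, match="single-class"):
            train_classifier(ModelSpec(kind="gbm"), table, ["informative"])

    def test_sequences_split_at_long_gaps(self):
        table = make_synthetic_table(n_participants=1, windows_per_night=10, seed=9)
        table = table[~table["window_index"].isin([4, 5])]  # 2-window hole
        seqs = build_sequences(table, ["informative"])
        assert len(seqs) == 2
        assert seqs[0].window_index.tolist() == [0, 1, 2, 3]


class TestSelection:
    def test_planted_informative_feature_survives(self):
        table = make_synthetic_table(
            n_participants=10, windows_per_night=100, effect=4.0, seed=10
        )
        trace = backward_greedy_selection(
            table, ["informative", "noise_0", "noise_1", "noise_2"], seed=0
        )
        assert "informative" in trace.final_subset
        assert len(trace.final_subset) < 4

    def test_duplicate_feature_resolved_to_single_copy(self):
        table = make_synthetic_table(n_participants=8, windows_per_night=60, seed=11)
        table["informative_copy"] = table["informative"]
        trace = backward_greedy_selection(
            table, ["informative", "informative_copy"], seed=0
        )
        assert len(trace.final_subset) == 1

    def test_round_one_trains_one_model_per_feature(self, monkeypatch):
        calls = []
        monkeypatch.setattr(
            selection_mod,
            "_cv_f1",
            lambda X, y, groups, cols, n_folds, seed: calls.append(len(cols)) or 0.5,
        )
        table = make_synthetic_table(n_participants=4, windows_per_night=10, seed=12)
        names = ["informative", "noise_0", "noise_1", "noise_2"]
        backward_greedy_selection(table, names, seed=0)
        k = len(names)
        # one scoring call for the full set, then k candidate models in round 1
        assert calls[0] == k
        assert calls[1 : 1 + k] == [k - 1] * k

    def test_fewer_than_two_features_rejected(self):
        table = make_synthetic_table(n_participants=4, seed=13)
        with pytest.raises(ValueError):
            backward_greedy_selection(table, ["informative"], seed=0)
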