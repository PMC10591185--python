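"""Ensemble training, majority voting, and the dual-model intersection."""

import itertools

import numpy as np
import pytest

from methsemble import encode, learn, metrics, simdata
from methsemble.learn import (BaseModelConfig, PredictionResult,
                              intersect_calls, predict, predict_features,
                              train_ensemble)
from methsemble.seqio import SequenceWindow
from oracles import majority_oracle


def small_training_set(n=60, seed=0):
    bench = simdata.generate_benchmark(n, n, 1.0, seed=seed)
    return encode.encode_matrix(bench.windows), bench.labels, bench


class TestConfig:
    def test_defaults_match_method_hyperparameters(self):
        cfg = BaseModelConfig()
        assert cfg.rf_n_trees == 500 and cfg.rf_vars_per_split == 5
        assert cfg.gb_n_trees == 150 and cfg.gb_depth == 3
        assert cfg.gb_shrinkage == 0.1 and cfg.gb_subsample == 0.5
        assert cfg.svm_c == 1.0

    def test_hash_is_stable_and_sensitive(self):
        assert BaseModelConfig().hash() == BaseModelConfig().hash()
        assert BaseModelConfig().hash() != BaseModelConfig(svm_c=2.0).hash()

    def test_non_positive_hyperparameter_rejected(self):
        with pytest.raises(ValueError):
            BaseModelConfig(gb_shrinkage=0)


class TestTrainEnsemble:
    def test_smoke_all_three_models_fit(self):
        X, y, _ = small_training_set()
        model = train_ensemble(X, y, species_tag="rice", seed=1)
        assert model.metadata["n_pos"] == model.metadata["n_neg"] == 60
        for m in (model.svm, model.rf, model.gb):
            assert hasattr(m, "predict")

    def test_deterministic_given_seed(self):
        X, y, bench = small_training_set(seed=2)
        a = train_ensemble(X, y, seed=5)
        b = train_ensemble(X, y, seed=5)
        assert a.metadata["config_hash"] == b.metadata["config_hash"]
        test = simdata.generate_benchmark(30, 30, 1.0, seed=3)
        Xt = encode.encode_matrix(test.windows)
        assert (predict_features(a, Xt)[1] == predict_features(b, Xt)[1]).all()

    def test_absent_selected_feature_named_in_error(self):
        X, y, _ = small_training_set()
        with pytest.raises(ValueError, match="NOPE"):
            train_ensemble(X, y, selected_features=["NOPE"])

    def test_single_class_rejected(self):
        X, y, _ = small_training_set()
        with pytest.raises(ValueError, match="single class"):
            train_ensemble(X, np.ones_like(y))

    def test_tiny_sample_rejected(self):
        X, y, _ = small_training_set()
        with pytest.raises(ValueError, match="at least 10"):
            train_ensemble(X.iloc[:6], y[:6])

    def test_imbalance_warning(self):
        X, y, _ = small_training_set(n=60)
        y = y.copy()
        y[10:60] = 0  # 10 pos vs 110 neg > 4:1
        with pytest.warns(UserWarning, match="imbalance"):
            train_ensemble(X, y)

    def test_save_load_round_trip(self, tmp_path, scan_model_pair):
        model, _ = scan_model_pair
        p = tmp_path / "model.joblib"
        model.save(p)
        back = learn.EnsembleModel.load(p)
        assert back.selected_features == model.selected_features
        assert back.metadata == model.metadata


class TestPredict:
    def test_vote_triples_match_majority_oracle(self):
        # Eq.-style mean-of-votes call versus brute-force majority, all 8 cases
        for votes in itertools.product([0, 1], repeat=3):
            score = sum(votes) / 3
            call = score >= 2 / 3
            assert call == majority_oracle(votes)

    def test_scores_quantized_and_calls_thresholded(self, scan_model_pair):
        model, _ = scan_model_pair
        test = simdata.generate_benchmark(40, 40, 0.5, seed=9)
        preds = predict(model, test.windows)
        allowed = {0.0, 1 / 3, 2 / 3, 1.0}
        for p in preds:
            assert p.score in allowed
            assert p.call == (p.score >= 2 / 3)
            assert p.score == sum(p.votes) / 3

    def test_empty_window_list(self, scan_model_pair):
        assert predict(scan_model_pair[0], []) == []

    def test_incompatible_feature_matrix_rejected(self, scan_model_pair):
        model, _ = scan_model_pair
        X = encode.encode_matrix(["A" * 41])
        with pytest.raises(ValueError, match="missing"):
            predict_features(model, X.iloc[:, :10])

    def test_ensemble_not_worse_than_worst_base_model(self):
        # ten seeds at desk scale: the majority vote should never fall below
        # the weakest of its three members on the same test set
        for seed in range(10):
            train = simdata.generate_benchmark(200, 200, 0.9, seed=30 + seed)
            test = simdata.generate_benchmark(100, 100, 0.9, seed=60 + seed)
            Xtr = encode.encode_matrix(train.windows)
            Xte = encode.encode_matrix(test.windows)
            model = train_ensemble(Xtr, train.labels, seed=30 + seed)
            votes, _, calls = predict_features(model, Xte)
            ens_acc = np.mean(calls == test.labels)
            base_accs = [np.mean(votes[:, i] == test.labels) for i in range(3)]
            assert ens_acc >= min(base_accs) - 1e-12


class TestIntersectCalls:
    def _pred(self, acc, idx, score, call):
        w = SequenceWindow(acc, idx, (idx - 1) * 41 + 1, idx * 41, "A" * 41)
        return PredictionResult(w, None, score, call)

    def test_intersection_truth_table(self):
        a = [self._pred("g", 1, 1.0, True), self._pred("g", 2, 1.0, True),
             self._pred("g", 3, 0.0, False)]
        b = [self._pred("g", 1, 2 / 3, True), self._pred("g", 2, 0.0, False),
             self._pred("g", 3, 0.0, False)]
        out = intersect_calls(a, b)
        assert [p.call for p in out] == [True, False, False]
        assert out[0].score == 2 / 3  # min of the two scores

    def test_intersection_subset_of_each_input(self):
        rng = np.random.default_rng(4)
        a = [self._pred("g", i + 1, s, s >= 2 / 3)
             for i, s in enumerate(rng.choice([0, 1 / 3, 2 / 3, 1.0], 30))]
        b = [self._pred("g", i + 1, s, s >= 2 / 3)
             for i, s in enumerate(rng.choice([0, 1 / 3, 2 / 3, 1.0], 30))]
        out = intersect_calls(a, b)
        called = {p.window.window_index for p in out if p.call}
        assert called <= {p.window.window_index for p in a if p.call}
        assert called <= {p.window.window_index for p in b if p.call}

    def test_mismatched_windows_listed(self):
        a = [self._pred("g", 1, 1.0, True)]
        b = [self._pred("g", 2, 1.0, True)]
        with pytest.raises(ValueError, match="symmetric difference"):
            intersect_calls(a, b)
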