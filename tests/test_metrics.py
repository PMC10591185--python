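"""Evaluation metrics against analytic cases and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

from methsemble import metrics
from methsemble.metrics import ConfusionMatrix, confusion, evaluate, roc_auc, topsis
from oracles import auc_oracle, mcc_oracle, topsis_oracle


class TestConfusion:
    def test_perfect_agreement(self):
        cm = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_full_disagreement(self):
        cm = confusion([1, 0], [0, 1])
        assert (cm.fn, cm.fp) == (1, 1)

    def test_cells_conserve_n(self, rng):
        y = rng.integers(0, 2, 100)
        c = rng.integers(0, 2, 100)
        assert confusion(y, c).total == 100

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestEvaluate:
    def test_flawless_prediction(self):
        rep = evaluate(ConfusionMatrix(tp=50, tn=50, fp=0, fn=0))
        assert rep.mcc == 1.0 and rep.accuracy == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_fully_wrong_prediction(self):
        rep = evaluate(ConfusionMatrix(tp=0, tn=0, fp=10, fn=5))
        assert rep.mcc == -1.0

    def test_uniform_matrix_is_random_forecast(self):
        rep = evaluate(ConfusionMatrix(tp=25, tn=25, fp=25, fn=25))
        assert rep.mcc == 0.0 and rep.accuracy == 0.5

    def test_zero_marginal_flags(self):
        rep = evaluate(ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(rep.sensitivity)
        assert rep.mcc == 0.0 and rep.flags

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(0, 0, 0, 0)

    def test_against_direct_recomputation(self, rng):
        for _ in range(1000):
            y = rng.integers(0, 2, 40)
            c = rng.integers(0, 2, 40)
            if y.std() == 0 or c.std() == 0:
                continue
            rep = evaluate(confusion(y, c))
            assert math.isclose(rep.mcc, mcc_oracle(y, c), abs_tol=1e-12)
            assert math.isclose(rep.mcc, matthews_corrcoef(y, c), abs_tol=1e-9)
            assert rep.accuracy == np.mean(y == c)

    def test_mcc_class_swap_symmetry(self, rng):
        y = rng.integers(0, 2, 60)
        c = rng.integers(0, 2, 60)
        a = evaluate(confusion(y, c)).mcc
        b = evaluate(confusion(1 - y, 1 - c)).mcc
        assert math.isclose(a, b, abs_tol=1e-12)


class TestRocAuc:
    def test_constant_scorer_is_random(self):
        auc, _ = roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_perfect_ranking(self):
        y = [0, 0, 1, 1]
        auc, _ = roc_auc(y, y)
        assert auc == 1.0

    def test_antisymmetry(self, rng):
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        s = rng.random(50)
        a, _ = roc_auc(y, s)
        b, _ = roc_auc(y, -s)
        assert math.isclose(a + b, 1.0, abs_tol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.8])

    def test_roc_points_monotone(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.choice([0, 1 / 3, 2 / 3, 1.0], 100)  # quantized vote scores
        _, pts = roc_auc(y, s)
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()

    @pytest.mark.parametrize("n,quantized", [(20, False), (200, False),
                                             (200, True)])
    def test_matches_pairwise_oracle(self, rng, n, quantized):
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        s = (rng.choice([0, 1 / 3, 2 / 3, 1.0], n) if quantized
             else rng.random(n))
        auc, _ = roc_auc(y, s)
        assert math.isclose(auc, auc_oracle(y, s), abs_tol=1e-12)


class TestTopsis:
    def test_dominating_alternative_scores_one(self):
        df = pd.DataFrame([[0.9, 0.9], [0.1, 0.1]], index=["good", "bad"],
                          columns=["acc", "mcc"])
        res = topsis(df)
        assert res.scores[0] == 1.0 and res.scores[1] == 0.0
        assert list(res.ranks) == [1, 2]

    def test_matches_textbook_oracle_on_random_matrices(self, rng):
        for _ in range(25):
            X = rng.random((3, 4)) + 0.1
            df = pd.DataFrame(X, index=["m1", "m2", "m3"],
                              columns=list("abcd"))
            res = topsis(df)
            expect = topsis_oracle(X, [0.25] * 4, ["benefit"] * 4)
            assert np.abs(res.scores - expect).max() < 1e-12

    def test_duplicate_alternatives_tie_by_name(self):
        df = pd.DataFrame([[0.5, 0.5], [0.5, 0.5], [0.9, 0.9]],
                          index=["b", "a", "best"], columns=["x", "y"])
        res = topsis(df)
        scores = dict(zip(res.alternatives, res.scores))
        ranks = dict(zip(res.alternatives, res.ranks))
        assert scores["a"] == scores["b"]
        assert ranks["best"] == 1 and ranks["a"] == 2 and ranks["b"] == 3

    def test_scale_invariance_of_criteria(self, rng):
        X = rng.random((4, 3)) + 0.1
        df = pd.DataFrame(X, index=list("wxyz"), columns=list("abc"))
        scaled = df.copy()
        scaled["b"] *= 137.0  # vector normalization absorbs the rescaling
        assert np.allclose(topsis(df).scores, topsis(scaled).scores,
                           atol=1e-12)

    def test_cost_criterion_flips_direction(self):
        df = pd.DataFrame([[0.9], [0.1]], index=["hi", "lo"], columns=["err"])
        res = topsis(df, directions=["cost"])
        assert dict(zip(res.alternatives, res.ranks))["lo"] == 1

    def test_single_alternative_rejected(self):
        with pytest.raises(ValueError):
            topsis(pd.DataFrame([[1.0]], index=["only"], columns=["c"]))

    def test_zero_norm_column_skipped(self):
        df = pd.DataFrame([[0.0, 0.9], [0.0, 0.1]], index=["a", "b"],
                          columns=["dead", "live"])
        res = topsis(df)
        assert list(res.ranks) == [1, 2]
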