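"""OPLS-DA fit, prediction, cross-validation, permutation and cv-ANOVA."""

import numpy as np
import pandas as pd
import pytest

from nmrstrat.oplsda import (OplsdaModel, cross_validate, cv_anova,
                             fit_oplsda, misclassification_table, p_corr,
                             permutation_test, predict)


def _pls1_oracle(X, y01):
    """Independent textbook single-component PLS1 (centered data)."""
    Xc = X - X.mean(axis=0)
    yc = y01 - y01.mean()
    w = Xc.T @ yc / (yc @ yc)
    w = w / np.linalg.norm(w)
    t = Xc @ w
    p = Xc.T @ t / (t @ t)
    return w, t, p


def _separable(n=20, p=30, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.array(["a", "b"] * (n // 2))
    X[y == "b", :5] += gap
    return X, y


class TestFit:
    def test_zero_orth_equals_textbook_pls1(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            X = rng.normal(size=(10, 20))
            y = rng.integers(0, 2, 10)
            if len(np.unique(y)) < 2:
                continue
            model = fit_oplsda(X, y, n_orth=0)
            w, t, p = _pls1_oracle(X, (y == 1).astype(float))
            s = np.sign(w @ model.w_pred) or 1.0
            np.testing.assert_allclose(model.w_pred, s * w, atol=1e-10)
            np.testing.assert_allclose(model.t_pred, s * t, atol=1e-10)
            np.testing.assert_allclose(model.p_pred, s * p, atol=1e-10)

    def test_column_proportional_to_labels_has_pcorr_one(self):
        # single predictor proportional to the labels: t[1] is that column
        y = np.array([0, 1] * 8)
        X = (3.0 * y + 1.0).reshape(-1, 1)
        model = fit_oplsda(X, y, n_orth=0)
        assert model.p_corr[0] == pytest.approx(1.0, abs=1e-12)
        # with extra noise columns it stays the strongest correlate
        rng = np.random.default_rng(3)
        X2 = np.column_stack([X, rng.normal(size=(16, 5))])
        model2 = fit_oplsda(X2, y, n_orth=0)
        assert np.argmax(np.abs(model2.p_corr)) == 0
        assert np.all(np.abs(model2.p_corr) <= 1.0)

    def test_predictive_score_orthogonal_to_orthogonal_scores(self):
        X, y = _separable(seed=5)
        model = fit_oplsda(X, y, n_orth=2)
        for j in range(model.n_orth):
            t_o = model.t_orth[:, j]
            cos = model.t_pred @ t_o / (
                np.linalg.norm(model.t_pred) * np.linalg.norm(t_o))
            assert abs(cos) < 1e-8

    def test_variance_decomposition_bounded(self):
        X, y = _separable(seed=6)
        model = fit_oplsda(X, y, n_orth=2)
        assert model.r2x + model.r2x_orth.sum() <= 1.0 + 1e-12
        assert 0.0 <= model.r2y <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_oplsda(np.eye(4), np.zeros(4), n_orth=0)

    def test_excessive_orthogonal_components_rejected(self):
        X, y = _separable(n=6, p=4)
        with pytest.raises(ValueError, match="too large"):
            fit_oplsda(X, y, n_orth=5)

    def test_serialization_roundtrip_predicts_identically(self, tmp_path):
        X, y = _separable(seed=9)
        model = fit_oplsda(X, y, n_orth=1)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = OplsdaModel.from_json(path)
        t1, c1 = predict(model, X)
        t2, c2 = predict(back, X)
        np.testing.assert_allclose(t1, t2)
        assert list(c1) == list(c2)


class TestPredict:
    def test_training_rows_reproduce_training_scores(self):
        X, y = _separable(seed=11)
        model = fit_oplsda(X, y, n_orth=2)
        t_ps, calls = predict(model, X)
        np.testing.assert_allclose(t_ps, model.t_pred, atol=1e-10)

    def test_class_mean_rows_classified_correctly(self):
        X, y = _separable(seed=12)
        model = fit_oplsda(X, y, n_orth=1)
        means = np.vstack([X[y == "a"].mean(0), X[y == "b"].mean(0)])
        _, calls = predict(model, means)
        assert list(calls) == ["a", "b"]

    def test_column_mismatch_rejected(self):
        X, y = _separable()
        model = fit_oplsda(X, y, n_orth=0)
        with pytest.raises(ValueError, match="column mismatch"):
            predict(model, X[:, :-1])

    def test_all_zero_row_is_centering_projection(self):
        X, y = _separable(seed=13)
        model = fit_oplsda(X, y, n_orth=0)
        t_ps, _ = predict(model, np.zeros((1, X.shape[1])))
        assert t_ps[0] == pytest.approx(-(model.x_mean @ model.w_pred))


class TestCrossValidation:
    def test_separable_data_has_high_q2(self):
        X, y = _separable(gap=8.0, seed=20)
        assert cross_validate(X, y, n_orth=0) > 0.9

    def test_label_independent_data_has_nonpositive_mean_q2(self):
        q2s = []
        for rep in range(30):
            rng = np.random.default_rng(300 + rep)
            X = rng.normal(size=(20, 30))
            y = np.array([0, 1] * 10)
            q2s.append(cross_validate(X, y, n_orth=0))
        assert np.mean(q2s) < 0.0

    def test_duplicated_rows_with_opposite_labels_gives_zero_q2(self):
        rng = np.random.default_rng(31)
        base = rng.normal(size=(10, 8))
        X = np.vstack([base, base])
        y = np.array([0] * 10 + [1] * 10)
        q2 = cross_validate(X, y, n_orth=0, n_folds=5)
        assert q2 <= 0.05

    def test_q2_invariant_to_label_swap(self):
        X, y = _separable(seed=22)
        swapped = np.where(y == "a", "b", "a")
        assert cross_validate(X, y, 1) == pytest.approx(
            cross_validate(X, swapped, 1))

    def test_q2_never_exceeds_one(self):
        X, y = _separable(gap=50.0, seed=23)
        assert cross_validate(X, y, 1) <= 1.0


class TestPermutation:
    def test_same_seed_reproduces_null_distribution(self):
        X, y = _separable(seed=40)
        a = permutation_test(X, y, n_orth=0, n_perm=99, seed=7)
        b = permutation_test(X, y, n_orth=0, n_perm=99, seed=7)
        np.testing.assert_array_equal(a.r2y_perm, b.r2y_perm)
        np.testing.assert_array_equal(a.q2_perm, b.q2_perm)

    def test_separable_data_attains_minimum_p(self):
        X, y = _separable(gap=10.0, seed=41)
        report = permutation_test(X, y, n_orth=0, n_perm=199, seed=1)
        assert report.p_r2y == pytest.approx(1 / 200)
        assert report.p_q2 == pytest.approx(1 / 200)

    def test_seed_is_mandatory(self):
        X, y = _separable()
        with pytest.raises(ValueError, match="seed"):
            permutation_test(X, y, n_orth=0, n_perm=99)


class TestCvAnova:
    def test_near_zero_cv_residuals_highly_significant(self):
        y = np.array([0, 1] * 10)
        y_cv = y + np.random.default_rng(0).normal(0, 1e-4, 20)
        f, p = cv_anova(y, y_cv, n_components=1)
        assert p < 1e-6

    def test_null_predictions_nonsignificant(self):
        # CV predictions at chance level: PRESS ~ SStot, F <= ~0
        rng = np.random.default_rng(5)
        y = np.array([0, 1] * 10)
        y_cv = np.full(20, 0.5) + rng.normal(0, 0.05, 20)
        _, p = cv_anova(y, y_cv, n_components=1)
        assert p > 0.1

    def test_degrees_of_freedom_guard(self):
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError, match="too few samples"):
            cv_anova(y, np.zeros(4), n_components=3)


class TestMisclassification:
    @pytest.mark.parametrize("calls,truth,expected", [
        (["a", "a", "b", "b"], ["a", "a", "b", "b"], {"a": 100.0, "b": 100.0}),
        (["b", "b", "a", "a"], ["a", "a", "b", "b"], {"a": 0.0, "b": 0.0}),
        (["a", "a", "a", "b"], ["a", "a", "a", "a"], {"a": 75.0}),
    ])
    def test_percent_correct(self, calls, truth, expected):
        table = misclassification_table(calls, truth)
        for cls, pct in expected.items():
            assert table.loc[cls, "percent_correct"] == pytest.approx(pct)

    def test_label_outside_model_classes_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            misclassification_table(["a", "c"], ["a", "b"],
                                    classes=("a", "b"))


def test_p_corr_identities():
    rng = np.random.default_rng(60)
    X, y = _separable(seed=61)
    model = fit_oplsda(X, y, n_orth=0)
    # variable equal to t[1] correlates perfectly; orthogonal noise ~ 0
    X2 = X.copy()
    X2[:, 0] = model.t_pred
    vals = p_corr(model, X2)
    assert vals[0] == pytest.approx(1.0)
    assert np.all(np.abs(vals) <= 1.0)
    # zero-variance column -> 0 by convention
    X2[:, 1] = 2.5
    assert p_corr(model, X2)[1] == 0.0
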