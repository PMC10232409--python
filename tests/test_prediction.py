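import numpy as np
import pytest

from connectotype import prediction as pred
from connectotype.connectome import feature_index_table
from connectotype.qc import ValidationError


def _confounds(rng, n):
    return np.column_stack([rng.normal(72, 6, n), rng.integers(0, 2, n)])


class TestResidualize:
    def test_train_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(0)
        n = 60
        X = rng.normal(0, 1, (n, 30))
        C = _confounds(rng, n)
        tr, te = np.arange(40), np.arange(40, 60)
        ftr, fte = pred.residualize_train_apply(X, C, tr, te)
        for c in range(2):
            col = C[tr, c] - C[tr, c].mean()
            r = ftr.T @ col / (np.linalg.norm(ftr, axis=0) * np.linalg.norm(col) + 1e-30)
            assert np.all(np.abs(r) < 1e-10)

    def test_feature_equal_to_confound_zeroed_on_train(self):
        rng = np.random.default_rng(1)
        n = 30
        C = _confounds(rng, n)
        X = (2.0 * C[:, 0])[:, None]
        tr, te = np.arange(20), np.arange(20, 30)
        ftr, fte = pred.residualize_train_apply(X, C, tr, te)
        np.testing.assert_allclose(ftr, 0.0, atol=1e-10)
        np.testing.assert_allclose(fte, 0.0, atol=1e-10)

    def test_overlapping_indices_rejected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (10, 3))
        with pytest.raises(ValidationError):
            pred.residualize_train_apply(X, _confounds(rng, 10),
                                         np.arange(6), np.arange(5, 10))

    def test_target_residualized_with_train_coefficients(self):
        rng = np.random.default_rng(3)
        n = 50
        C = _confounds(rng, n)
        y = 3.0 + 0.5 * C[:, 0] + rng.normal(0, 0.1, n)
        X = rng.normal(0, 1, (n, 5))
        tr, te = np.arange(40), np.arange(40, 50)
        _, _, ytr, yte = pred.residualize_train_apply(X, C, tr, te, scores=y)
        assert np.abs(ytr).max() < 1.0      # age effect removed
        assert abs(np.corrcoef(ytr, C[tr, 0])[0, 1]) < 1e-8


class TestSelectFeaturesTtest:
    def test_strong_group_difference_selected(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (80, 20))
        labels = np.repeat([0, 1], 40)
        X[labels == 0, 7] -= 5.0
        X[labels == 1, 7] += 5.0
        sel = pred.select_features_ttest(X, labels, alpha=0.001)
        assert 7 in sel

    def test_null_false_selection_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (40, 10000))
        labels = np.repeat([0, 1], 20)
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = pred.select_features_ttest(X, labels, alpha=0.01)
        frac = len(sel) / 10000
        assert 0.005 < frac < 0.02

    def test_alpha_one_selects_everything(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (20, 15))
        sel = pred.select_features_ttest(X, np.repeat([0, 1], 10), alpha=1.0)
        assert len(sel) == 15

    def test_empty_selection_falls_back_with_warning(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (12, 30))
        with pytest.warns(UserWarning, match="falling back"):
            sel = pred.select_features_ttest(X, np.repeat([0, 1], 6), alpha=1e-12)
        assert len(sel) == 10


class TestClassifyCV:
    def _separable(self, seed, n_per=60, n_feat=100, gap=2.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (2 * n_per, n_feat))
        labels = np.repeat(["a", "b"], n_per)
        X[:n_per, :5] -= gap
        X[n_per:, :5] += gap
        return X, labels, _confounds(rng, 2 * n_per)

    def test_planted_separation_gives_high_auc(self):
        X, labels, C = self._separable(8)
        rep = pred.classify_cv(X, labels, C, k=5, seed=0)
        assert rep.auc >= 0.95 and rep.acc >= 0.9
        assert 0 <= rep.sen <= 1 and 0 <= rep.spe <= 1

    def test_permuted_labels_give_chance_auc(self):
        X, labels, C = self._separable(9, n_per=40, n_feat=50)
        rng = np.random.default_rng(10)
        aucs = []
        import warnings
        for i in range(10):
            perm = rng.permutation(labels)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    aucs.append(pred.classify_cv(X, perm, C, k=5, seed=i).auc)
            except ValidationError:
                continue
        assert 0.35 < np.mean(aucs) < 0.65

    def test_duplication_invariance(self):
        X, labels, C = self._separable(11, n_per=30, n_feat=40)
        rep1 = pred.classify_cv(X, labels, C, k=5, seed=3)
        rep2 = pred.classify_cv(np.vstack([X, X]), np.concatenate([labels, labels]),
                                np.vstack([C, C]), k=5, seed=3)
        assert abs(rep1.auc - rep2.auc) < 0.1


class TestPredictSvrLoocv:
    def test_noise_free_single_connection_recovered(self):
        rng = np.random.default_rng(12)
        n, f = 60, 45
        X = rng.normal(0, 0.3, (n, f))
        y = 4.0 * X[:, 17]
        C = np.column_stack([np.full(n, 72.0), np.zeros(n)])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = pred.predict_svr_loocv(X, y, C)
        assert rep.r > 0.99
        assert np.argmax(np.abs(rep.mean_weights)) == 17

    def test_shuffled_scores_give_null_r(self):
        rng = np.random.default_rng(13)
        n, f = 120, 60
        X = rng.normal(0, 0.3, (n, f))
        y = 4.0 * X[:, 5] + rng.normal(0, 0.5, n)
        C = _confounds(rng, n)
        hits = 0
        for i in range(5):
            perm = np.random.default_rng(100 + i).permutation(y)
            rep = pred.predict_svr_loocv(X, perm, C)
            hits += abs(rep.r) < 0.25
        assert hits >= 4

    def test_constant_features_rejected(self):
        X = np.ones((10, 5))
        y = np.arange(10.0)
        with pytest.raises(ValidationError):
            pred.predict_svr_loocv(X, y, np.zeros((10, 2)))

    def test_leakage_guard_test_score_cannot_change_own_prediction(self):
        rng = np.random.default_rng(14)
        n, f = 20, 15
        X = rng.normal(0, 0.3, (n, f))
        y = 3.0 * X[:, 2] + rng.normal(0, 0.3, n)
        C = _confounds(rng, n)
        rep1 = pred.predict_svr_loocv(X, y, C)
        y2 = y.copy()
        y2[7] += 100.0
        rep2 = pred.predict_svr_loocv(X, y2, C)
        assert rep1.predicted[7] == pytest.approx(rep2.predicted[7], abs=1e-8)


class TestEvaluateAndPermutation:
    def test_perfect_and_inverse(self):
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        assert pred.evaluate_prediction(y, y) == pytest.approx(1.0)
        assert pred.evaluate_prediction(-y, y) == pytest.approx(-1.0)

    def test_five_point_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        am, bm = a - 3.0, b - 3.0
        expected = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
        assert pred.evaluate_prediction(a, b) == pytest.approx(expected)

    def test_add_one_estimator_bounds(self):
        rng = np.random.default_rng(15)
        n = 12
        X = rng.normal(0, 0.3, (n, 8))
        y = rng.normal(0, 1, n)
        C = np.column_stack([rng.normal(72, 5, n), rng.integers(0, 2, n)])
        # an unbeatable observed r gives the add-one lower bound
        p, rs = pred.permutation_test(X, y, C, r_observed=2.0, n_perm=19, seed=0)
        assert p == pytest.approx(1 / 20)
        # an observed r below every permutation gives p = 1
        p, _ = pred.permutation_test(X, y, C, r_observed=-2.0, n_perm=19, seed=0)
        assert p == pytest.approx(1.0)

    def test_raw_estimator_fraction(self):
        rng = np.random.default_rng(16)
        n = 12
        X = rng.normal(0, 0.3, (n, 8))
        y = rng.normal(0, 1, n)
        C = np.column_stack([rng.normal(72, 5, n), rng.integers(0, 2, n)])
        p, rs = pred.permutation_test(X, y, C, r_observed=np.median(np.r_[0.0]),
                                      n_perm=10, seed=1, estimator="raw")
        assert p == np.sum(rs >= 0.0) / 10


class TestContributionAnalysis:
    def test_single_nonzero_connection(self):
        table = feature_index_table(5)
        W = np.zeros((4, len(table)))
        W[:, 3] = 0.5
        net = np.array([1, 1, 2, 2, 3])
        out = pred.contribution_analysis(W, table, net, np.array([1, 2, 3]))
        assert list(out.top_connections) == [3]
        i, j = table[3]
        assert out.roi_contribution[i - 1] == out.roi_contribution[j - 1] == 0.5

    def test_hundred_selected_gives_top_ten(self):
        rng = np.random.default_rng(17)
        table = feature_index_table(20)   # 190 features
        W = np.zeros((6, 190))
        chosen = rng.choice(190, 100, replace=False)
        W[:, chosen] = rng.normal(0, 1, (6, 100))
        net = np.repeat(np.arange(1, 5), 5)
        out = pred.contribution_analysis(W, table, net, np.array([1, 1, 2, 2]))
        assert len(out.top_connections) == 10
        # top set holds the largest |mean weight| among selected
        mw = np.abs(W.mean(axis=0))
        assert set(out.top_connections) == set(np.argsort(-mw)[:10])

    def test_all_zero_weights_empty_report(self):
        table = feature_index_table(4)
        with pytest.warns(UserWarning, match="all-zero"):
            out = pred.contribution_analysis(np.zeros((3, 6)), table,
                                             np.array([1, 1, 2, 2]), np.array([1, 2]))
        assert len(out.top_connections) == 0

    def test_network_split_within_vs_between(self):
        table = feature_index_table(4)
        net = np.array([1, 1, 2, 2])
        can = np.array([1, 2])
        W = np.zeros((2, 6))
        f_within = int(np.flatnonzero((table[:, 0] == 1) & (table[:, 1] == 2))[0])
        f_between = int(np.flatnonzero((table[:, 0] == 1) & (table[:, 1] == 3))[0])
        W[:, f_within] = 1.0
        W[:, f_between] = 2.0
        out = pred.contribution_analysis(W, table, net, can, percentile=0.0)
        assert out.n_top_within == 1 and out.n_top_between == 1
        assert out.network_within[1] == pytest.approx(1.0)
        assert out.network_between[1] == pytest.approx(2.0)
        assert out.network_between[2] == pytest.approx(2.0)
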