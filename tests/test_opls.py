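import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipodisc import autoscale, bayes_thresholds, fit_opls_da, predict_opls, vip
from lipodisc.opls import OplsError


def nipals_pls1(X, y, n_components):
    """Independent NIPALS PLS1 oracle: fitted values after A components."""
    Xd = X.copy()
    yd = y - y.mean()
    yhat = np.full(len(y), y.mean())
    for _ in range(n_components):
        w = Xd.T @ yd
        w /= np.linalg.norm(w)
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        q = yd @ t / tt
        Xd -= np.outer(t, p)
        yd = yd - q * t
        yhat = yhat + q * t
    return yhat


def random_problem(seed, n=40, p=15):
    rng = np.random.default_rng(seed)
    X, _ = autoscale(rng.normal(size=(n, p)))
    y = np.zeros(n)
    y[: n // 2] = 1.0
    return X, y


class TestFit:
    def test_zero_orth_equals_single_component_pls1(self):
        X, y = random_problem(0)
        model = fit_opls_da(X, y, n_orth=0)
        assert np.abs(model.fitted() - nipals_pls1(X, y, 1)).max() < 1e-10

    def test_response_equal_to_one_column_concentrates_weight(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(30, 8))
        y01 = (rng.random(30) < 0.5).astype(float)
        yc = y01 - y01.mean()
        # other columns made exactly orthogonal to the response; column 3
        # *is* the (scaled) response
        raw -= np.outer(yc, raw.T @ yc) / (yc @ yc)
        raw[:, 3] = yc
        X, _ = autoscale(raw)
        model = fit_opls_da(X, y01, n_orth=0)
        assert abs(model.w_pred[3]) > 0.999
        r = np.corrcoef(model.fitted(), y01)[0, 1]
        assert r > 0.999

    @pytest.mark.parametrize("n_orth", [1, 2, 3])
    def test_equivalence_with_pls1_oracle(self, n_orth):
        """OPLS (1 pred + k orth) fitted values = PLS1 with k+1 components."""
        for seed in range(15):
            X, y = random_problem(seed)
            model = fit_opls_da(X, y, n_orth=n_orth)
            oracle = nipals_pls1(X, y, n_orth + 1)
            assert np.abs(model.fitted() - oracle).max() < 1e-8

    def test_equivalence_with_sklearn_pls(self):
        """Second, fully independent route: scikit-learn's PLS regression."""
        from sklearn.cross_decomposition import PLSRegression

        for seed in range(5):
            X, y = random_problem(seed, n=30, p=10)
            for n_orth in (0, 1, 2):
                model = fit_opls_da(X, y, n_orth=n_orth)
                ref = PLSRegression(n_components=n_orth + 1, scale=False).fit(X, y)
                assert np.abs(model.fitted() - ref.predict(X).ravel()).max() < 1e-8

    def test_orthogonal_scores_uncorrelated_with_response(self):
        X, y = random_problem(2)
        model = fit_opls_da(X, y, n_orth=3)
        yc = y - y.mean()
        for a in range(3):
            t_o = model.T_orth[:, a]
            assert abs(t_o @ yc) < 1e-8 * np.linalg.norm(t_o) * np.linalg.norm(yc)
            assert abs(t_o @ model.t_pred) < 1e-8 * np.linalg.norm(t_o) * np.linalg.norm(
                model.t_pred
            )

    def test_single_class_rejected(self):
        X, _ = random_problem(3)
        with pytest.raises(OplsError, match="both classes"):
            fit_opls_da(X, np.ones(X.shape[0]), n_orth=1)

    def test_excessive_orth_components_rejected(self):
        rng = np.random.default_rng(4)
        X, _ = autoscale(rng.normal(size=(8, 3)))
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        with pytest.raises(OplsError):
            fit_opls_da(X, y, n_orth=5)


class TestPredict:
    def test_training_matrix_reproduces_fitted(self):
        X, y = random_problem(5)
        model = fit_opls_da(X, y, n_orth=2)
        assert np.allclose(predict_opls(model, X), model.fitted())

    def test_mean_profile_predicts_mean_response(self):
        X, y = random_problem(6)
        model = fit_opls_da(X, y, n_orth=2)
        yhat = predict_opls(model, np.zeros((1, X.shape[1])))
        assert yhat[0] == pytest.approx(y.mean())

    def test_consistent_feature_permutation_invariance(self):
        X, y = random_problem(7)
        model = fit_opls_da(X, y, n_orth=2)
        perm = np.random.default_rng(0).permutation(X.shape[1])
        model_p = fit_opls_da(X[:, perm], y, n_orth=2)
        assert np.allclose(
            predict_opls(model, X), predict_opls(model_p, X[:, perm]), atol=1e-10
        )

    def test_feature_count_mismatch(self):
        X, y = random_problem(8)
        model = fit_opls_da(X, y, n_orth=1)
        with pytest.raises(OplsError, match="mismatch"):
            predict_opls(model, X[:, :5])


class TestVip:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_orth=st.integers(0, 3))
    def test_squares_sum_to_feature_count(self, seed, n_orth):
        X, y = random_problem(seed)
        model = fit_opls_da(X, y, n_orth=n_orth)
        assert (vip(model) ** 2).sum() == pytest.approx(X.shape[1], abs=1e-8)

    def test_equal_weights_give_unit_vip(self):
        # two identical informative columns share the weight equally
        rng = np.random.default_rng(9)
        y = np.repeat([0.0, 1.0], 15)
        base = y - y.mean() + rng.normal(0, 0.1, 30)
        X, _ = autoscale(np.column_stack([base, base]))
        model = fit_opls_da(X, y, n_orth=0)
        assert np.allclose(vip(model), 1.0, atol=1e-8)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(10)
        X, _ = autoscale(rng.normal(size=(30, 8)))
        y = (rng.random(30) < 0.5).astype(float)
        model = fit_opls_da(X, y, n_orth=0)
        # predictive-only VIP: sqrt(p · SSY_pred (w_j/||w||)^2 / SSY_pred)
        w = model.w_pred
        expected = np.sqrt(8 * (w / np.linalg.norm(w)) ** 2)
        assert np.abs(vip(model) - expected).max() < 1e-10


class TestBayesThresholds:
    @staticmethod
    def gaussian_samples(m1, s1, m0, s0, n1=200, n0=200, seed=0):
        rng = np.random.default_rng(seed)
        yhat = np.concatenate([rng.normal(m1, s1, n1), rng.normal(m0, s0, n0)])
        labels = np.array(["SCH"] * n1 + ["BD"] * n0)
        return yhat, labels

    def test_symmetric_classes_threshold_half(self):
        yhat, labels = self.gaussian_samples(0.8, 0.1, 0.2, 0.1, seed=1)
        thr = bayes_thresholds(yhat, labels)
        assert thr.threshold_sch == pytest.approx(0.5, abs=0.02)
        assert thr.threshold_sch + thr.threshold_bd == pytest.approx(1.0, abs=1e-8)

    def test_unequal_priors_match_closed_form(self):
        yhat, labels = self.gaussian_samples(0.8, 0.1, 0.2, 0.1, n1=300, n0=100, seed=2)
        thr = bayes_thresholds(yhat, labels)
        m1, s1, pi1 = thr.class_densities["SCH"]
        m0, s0, pi0 = thr.class_densities["BD"]
        s2 = ((s1**2) + (s0**2)) / 2  # sds nearly equal by construction
        closed = (m1 + m0) / 2 + s2 * np.log(pi0 / pi1) / (m1 - m0)
        assert thr.threshold_sch == pytest.approx(closed, abs=5e-3)
        # boundary shifts toward the rarer (BD) class mean
        assert thr.threshold_sch < (m1 + m0) / 2

    def test_boundary_minimizes_bayes_risk_grid_oracle(self):
        yhat, labels = self.gaussian_samples(0.75, 0.12, 0.25, 0.08, seed=3)
        thr = bayes_thresholds(yhat, labels)
        m1, s1, pi1 = thr.class_densities["SCH"]
        m0, s0, pi0 = thr.class_densities["BD"]
        grid = np.linspace(-0.5, 1.5, 200001)
        from scipy.stats import norm

        risk = pi1 * norm.cdf(grid, m1, s1) + pi0 * norm.sf(grid, m0, s0)
        assert abs(thr.threshold_sch - grid[np.argmin(risk)]) < 1e-3

    def test_classification_equals_argmax_posterior(self):
        yhat, labels = self.gaussian_samples(0.7, 0.15, 0.3, 0.1, seed=4)
        thr = bayes_thresholds(yhat, labels)
        m1, s1, pi1 = thr.class_densities["SCH"]
        m0, s0, pi0 = thr.class_densities["BD"]
        from scipy.stats import norm

        post1 = pi1 * norm.pdf(yhat, m1, s1)
        post0 = pi0 * norm.pdf(yhat, m0, s0)
        expected = np.where(post1 >= post0, "SCH", "BD")
        assert (thr.classify(yhat) == expected).all()

    def test_tiny_class_rejected(self):
        yhat = np.array([0.1, 0.9, 0.8, 0.7])
        labels = np.array(["BD", "SCH", "SCH", "SCH"])
        with pytest.raises(OplsError, match="fewer than 2"):
            bayes_thresholds(yhat, labels)
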