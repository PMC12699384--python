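import numpy as np
import pytest
from scipy.stats import norm

from revaci.estimation import (ClassificationImageModel, aci_correlation,
                               aci_weighted_sum, build_gaussian_basis,
                               deviance, glm_fit, make_folds, search_lambda)
from revaci.representation import StimulusTensor, zscore_pixels


def synthetic_probit_data(n=600, nf=6, nt=8, seed=0, signal=0.6):
    """Trials drawn from the probit model itself (ground truth known)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, nf, nt))
    w = np.zeros((nf, nt))
    w[2:4, 3:6] = signal / np.sqrt(6)
    eta = X.reshape(n, -1) @ w.ravel() + 0.15
    r = (rng.random(n) < norm.cdf(eta)).astype(int)
    return X, r, w


class TestCorrelationAndWeightedSum:
    def test_self_correlated_pixel_dominates(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((400, 3, 3))
        j = (1, 2)
        r = (X[:, j[0], j[1]] > np.median(X[:, j[0], j[1]])).astype(int)
        res = aci_correlation(X, r)
        assert np.unravel_index(np.argmax(res.weights), res.shape) == j

    def test_null_responses_small_weights(self):
        rng = np.random.default_rng(1)
        n = 1000
        X = rng.standard_normal((n, 4, 4))
        r = rng.integers(0, 2, n)
        res = aci_correlation(X, r)
        assert np.max(np.abs(res.weights)) < 5 / np.sqrt(n)

    def test_proportional_after_zscore(self):
        # with per-pixel z-scoring the two estimators are the same image up
        # to a positive factor, irrespective of response balance
        rng = np.random.default_rng(2)
        t = StimulusTensor(rng.gamma(2, 1, (300, 5, 6)),
                           np.arange(5), np.arange(6))
        z = zscore_pixels(t)
        r = rng.integers(0, 2, 300)
        a = aci_correlation(z, r).weights.ravel()
        b = aci_weighted_sum(z, r).weights.ravel()
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos > 0.9999

    def test_two_trial_weighted_sum_exact(self):
        X = np.array([[[1.0, 2.0]], [[4.0, 0.5]]])
        res = aci_weighted_sum(X, [0, 1])
        assert np.allclose(res.weights, X[1] - X[0])

    def test_label_swap_negates(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 2, 2))
        r = rng.integers(0, 2, 50)
        a = aci_weighted_sum(X, r).weights
        b = aci_weighted_sum(X, 1 - r).weights
        assert np.allclose(a, -b)

    def test_single_class_errors(self):
        X = np.random.default_rng(0).standard_normal((10, 2, 2))
        with pytest.raises(ValueError):
            aci_weighted_sum(X, np.ones(10, int))
        with pytest.raises(ValueError):
            aci_correlation(X, np.zeros(10, int))


class TestGaussianBasis:
    def test_element_count_decreases_with_level(self):
        basis = build_gaussian_basis(16, 24, 2, 5)
        counts = [sum(1 for e in basis.elements if e[4] == lvl)
                  for lvl in range(2, 6)]
        assert all(a > b for a, b in zip(counts, counts[1:]))

    def test_columns_unit_peak_nonnegative(self):
        basis = build_gaussian_basis(8, 8)
        assert np.all(basis.design >= 0)
        assert np.allclose(basis.design.max(axis=0), 1.0)

    def test_planted_bump_reconstructed_by_own_column(self):
        basis = build_gaussian_basis(16, 16, 3, 3)
        cf, ct, sf, st, _ = basis.elements[5]
        ff, tt = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        bump = np.exp(-0.5 * (((ff - cf) / sf) ** 2 + ((tt - ct) / st) ** 2))
        resid = bump.ravel() - basis.design[:, 5]
        assert np.linalg.norm(resid) / np.linalg.norm(bump) < 1e-6

    def test_bad_levels(self):
        with pytest.raises(ValueError):
            build_gaussian_basis(8, 8, 5, 2)


class TestGlmFit:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        r = (rng.random(500) < 0.7).astype(int)
        X = np.zeros((500, 2, 2))  # no informative pixels
        res = glm_fit(X, r, penalty="none")
        assert res.intercept == pytest.approx(norm.ppf(r.mean()), abs=1e-6)

    def test_matches_brute_force_grid_two_pixels(self):
        # exhaustive (w1, w2, c) grid as an independent likelihood oracle
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 2, 1))
        eta = 0.8 * X[:, 0, 0] - 0.5 * X[:, 1, 0] + 0.2
        r = (rng.random(200) < norm.cdf(eta)).astype(int)
        fit = glm_fit(X, r, penalty="none")
        dev_fit = fit.deviance(X, r)

        grid = np.linspace(-2, 2, 81)
        Xm = X.reshape(200, 2)
        best = np.inf
        for w1 in grid:
            eta1 = w1 * Xm[:, 0]
            for w2 in grid:
                eta2 = eta1 + w2 * Xm[:, 1]
                for c in grid[::4]:
                    p = norm.cdf(eta2 + c)
                    d = deviance(r, p)
                    best = min(best, d)
        assert dev_fit <= best + 1e-3

    def test_matches_statsmodels_probit(self):
        # independent implementation cross-check on the same likelihood
        sm = pytest.importorskip("statsmodels.api")
        X, r, _ = synthetic_probit_data(n=400, nf=3, nt=3, seed=6)
        fit = glm_fit(X, r, penalty="none")
        design = sm.add_constant(X.reshape(400, -1))
        ref = sm.GLM(r, design, family=sm.families.Binomial(
            sm.families.links.Probit())).fit()
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-4)
        assert np.allclose(fit.weights.ravel(), ref.params[1:], atol=1e-4)

    def test_l1_large_lambda_flat_image(self):
        X, r, _ = synthetic_probit_data(seed=7)
        res = glm_fit(X, r, penalty="l1_basis", lam=1e4)
        assert np.all(res.weights == 0)
        assert res.intercept == pytest.approx(norm.ppf(r.mean()), abs=1e-3)

    def test_l2_small_lambda_matches_ml(self):
        X, r, _ = synthetic_probit_data(n=400, nf=4, nt=5, seed=8)
        ml = glm_fit(X, r, penalty="none")
        l2 = glm_fit(X, r, penalty="l2_smooth", lam=1e-12)
        assert np.max(np.abs(l2.weights - ml.weights)) < 1e-3

    def test_l2_large_lambda_smooths(self):
        X, r, _ = synthetic_probit_data(seed=9)
        rough = glm_fit(X, r, penalty="l2_smooth", lam=1e-6).weights
        smooth = glm_fit(X, r, penalty="l2_smooth", lam=10.0).weights

        def roughness(w):
            return np.sum(np.diff(w, axis=0) ** 2) + np.sum(np.diff(w, axis=1) ** 2)

        assert roughness(smooth) < roughness(rough)

    def test_separation_warns(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((60, 2, 2))
        r = (X[:, 0, 0] > 0).astype(int)  # perfectly separable
        with pytest.warns(RuntimeWarning, match="separation"):
            res = glm_fit(X, r, penalty="none")
        assert not res.converged

    def test_negative_lambda_rejected(self):
        X, r, _ = synthetic_probit_data(n=50, nf=4, nt=4)
        with pytest.raises(ValueError):
            glm_fit(X, r, penalty="l1_basis", lam=-1.0)


class TestFolds:
    def test_partition_properties(self):
        rng = np.random.default_rng(0)
        r = rng.integers(0, 2, 103)
        folds = make_folds(103, 10, rng, r=r)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(103))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 2
        # stratification: both classes in every training complement
        for f in folds:
            train = np.setdiff1d(np.arange(103), f)
            assert len(np.unique(r[train])) == 2


class TestSearchLambda:
    def test_path_sorted_and_argmin(self, planted_lambda_path):
        lam, path = planted_lambda_path
        lams = [p[0] for p in path]
        assert lams == sorted(lams)
        devs = [p[1] for p in path]
        assert min(p[0] for p in path if p[1] == min(devs)) == lam

    def test_interior_minimum_on_simulated_observer(self, planted_session):
        # on 3,000 simulated trials the CV-deviance path is U-shaped:
        # both endpoints of the grid are strictly worse than the minimum
        _, tensor, r, _ = planted_session
        sub = tensor.subset(np.arange(3000))
        lam, path = search_lambda(sub, r[:3000], "l1_basis",
                                  rng=np.random.default_rng(2))
        devs = [p[1] for p in path]
        assert devs[0] > min(devs)
        assert devs[-1] > min(devs)
        assert 0 < lam < 5.0

    def test_requires_penalty(self):
        X, r, _ = synthetic_probit_data(n=60, nf=4, nt=4)
        with pytest.raises(ValueError):
            search_lambda(X, r, "none")


class TestModelFrontDoor:
    def test_from_arrays_and_fit_methods(self):
        X, r, w_true = synthetic_probit_data(n=500, nf=6, nt=8, seed=11)
        model = ClassificationImageModel(X, r, zscore=True)
        res = model.fit("correlation")
        assert res.method == "correlation"
        assert np.corrcoef(res.weights.ravel(), w_true.ravel())[0, 1] > 0.3
        txt = model.fit("glm").summary()
        assert "glm" in txt and "intercept" in txt

    def test_from_session_pipeline(self, small_session):
        session, _, _, _ = small_session
        from revaci.presets import tone_frontend
        model = ClassificationImageModel.from_session(
            session, repr_spec=tone_frontend(1.0))
        assert model.tensor.n_trials == session.n_trials  # no probes scheduled
        res = model.fit("weighted_sum")
        assert res.shape == model.tensor.data.shape[1:]
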