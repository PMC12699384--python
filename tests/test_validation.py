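import numpy as np
import pytest
from scipy.stats import norm

from revaci.estimation import ACIResult, aci_correlation, make_folds
from revaci.validation import (convergence_curve, cross_predict,
                               cross_validate, cue_to_noise_ratio, fdr_mask,
                               permutation_test)


def null_dataset(rng, n=300, nf=5, nt=5):
    X = rng.standard_normal((n, nf, nt))
    r = rng.integers(0, 2, n)
    while r.min() == r.max():
        r = rng.integers(0, 2, n)
    return X, r


class TestCrossValidate:
    def test_folds_partition(self):
        rng = np.random.default_rng(0)
        X, r = null_dataset(rng, n=103)
        rep = cross_validate(X, r, fit_spec="correlation", n_folds=10, rng=rng)
        all_idx = np.concatenate(rep.folds)
        assert sorted(all_idx) == list(range(103))
        sizes = [len(f) for f in rep.folds]
        assert max(sizes) - min(sizes) <= 2

    @pytest.mark.filterwarnings("ignore:probit fit drifting")
    def test_separable_data_high_accuracy(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((400, 4, 4))
        r = (X[:, 2, 2] > 0).astype(int)  # one pixel determines the response
        rep = cross_validate(X, r, fit_spec="glm", n_folds=5, rng=rng)
        assert rep.mean_accuracy > 95.0

    def test_null_data_chance_accuracy(self):
        rng = np.random.default_rng(2)
        X, r = null_dataset(rng, n=600)
        rep = cross_validate(X, r, fit_spec="correlation", n_folds=5, rng=rng)
        se = 100 * np.sqrt(0.25 / 600)
        assert abs(rep.mean_accuracy - 50.0) < 4 * se

    def test_too_many_folds(self):
        rng = np.random.default_rng(3)
        X, r = null_dataset(rng, n=10)
        with pytest.raises(ValueError):
            cross_validate(X, r, n_folds=8, rng=rng)


class TestCrossPredict:
    def test_zero_image_gives_intercept_only_deviance(self):
        rng = np.random.default_rng(4)
        X, r = null_dataset(rng, n=200)
        zero = ACIResult(np.zeros((5, 5)), 0.0, "weighted_sum",
                         np.arange(5), np.arange(5))
        folds = make_folds(200, 5, rng, r=r)
        rep = cross_predict(zero, X, r, folds)
        # Phi(0) = 0.5 everywhere -> deviance = 2 n ln 2 per fold
        assert rep.mean_deviance == pytest.approx(2 * 40 * np.log(2), rel=1e-9)

    def test_twin_observers_transfer_above_chance(self):
        # two datasets generated from the same underlying template
        rng = np.random.default_rng(5)
        w = np.zeros((4, 4))
        w[1:3, 1:3] = 0.8
        def simulate(seed):
            g = np.random.default_rng(seed)
            X = g.standard_normal((500, 4, 4))
            r = (g.random(500) < norm.cdf(X.reshape(500, -1) @ w.ravel())).astype(int)
            return X, r
        Xa, ra = simulate(10)
        Xb, rb = simulate(11)
        aci_a = ACIResult(w * 0.9, 0.0, "glm", np.arange(4), np.arange(4))
        folds = make_folds(500, 5, rng, r=rb)
        rep = cross_predict(aci_a, Xb, rb, folds)
        se = 100 * np.sqrt(0.25 / 500)
        assert rep.mean_accuracy > 50.0 + 3 * se

    def test_dim_mismatch(self):
        rng = np.random.default_rng(6)
        X, r = null_dataset(rng)
        bad = ACIResult(np.zeros((3, 3)), 0.0, "glm", np.arange(3), np.arange(3))
        with pytest.raises(ValueError, match="dims"):
            cross_predict(bad, X, r, [np.arange(10)])


class TestPermutationTest:
    def test_class_counts_preserved_and_shapes(self):
        rng = np.random.default_rng(7)
        X, r = null_dataset(rng, n=100)
        res = permutation_test(X, r, "correlation", n_perm=25, rng=rng)
        assert res.null_weights.shape == (25, 5, 5)
        assert res.lo.shape == res.hi.shape == res.mask.shape == (5, 5)
        assert np.all(res.lo <= res.hi)

    def test_null_coverage_near_ninety_percent(self):
        rng = np.random.default_rng(8)
        fracs = []
        for _ in range(10):
            X, r = null_dataset(rng, n=400)
            res = permutation_test(X, r, "correlation", n_perm=150, rng=rng)
            fracs.append(1 - res.fraction_significant)
        assert abs(100 * np.mean(fracs) - 90.0) < 3.0

    def test_planted_cue_detected(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(10):
            X = rng.standard_normal((400, 4, 4))
            r = (rng.random(400) < norm.cdf(1.5 * X[:, 1, 1])).astype(int)
            res = permutation_test(X, r, "correlation", n_perm=60, rng=rng)
            hits += bool(res.mask[1, 1])
        assert hits >= 9

    def test_small_nperm_warns(self):
        rng = np.random.default_rng(10)
        X, r = null_dataset(rng, n=60)
        with pytest.warns(RuntimeWarning, match="unstable"):
            permutation_test(X, r, "correlation", n_perm=10, rng=rng)


class TestCueToNoiseRatio:
    def make_aci(self, w):
        return ACIResult(w, 0.0, "correlation",
                         np.linspace(100, 3000, w.shape[0]),
                         np.linspace(0.05, 0.95, w.shape[1]))

    def test_uniform_magnitude_is_one(self):
        w = np.ones((10, 10))
        w[::2, 1::2] = -1.0
        aci = self.make_aci(w)
        assert cue_to_noise_ratio(aci, (200, 1000, 0.1, 0.4),
                                  (1500, 2900, 0.6, 0.9)) == 1.0

    def test_scale_invariant(self):
        rng = np.random.default_rng(11)
        w = rng.standard_normal((10, 10))
        aci1 = self.make_aci(w)
        aci2 = self.make_aci(-3.7 * w)
        cue, nul = (200, 1000, 0.1, 0.4), (1500, 2900, 0.6, 0.9)
        assert cue_to_noise_ratio(aci1, cue, nul) == pytest.approx(
            cue_to_noise_ratio(aci2, cue, nul))

    def test_zero_denominator_infinite(self):
        w = np.zeros((10, 10))
        w[0, 0] = 1.0
        aci = self.make_aci(w)
        with pytest.warns(RuntimeWarning):
            ratio = cue_to_noise_ratio(aci, (90, 110, 0.0, 0.1),
                                       (1500, 2900, 0.6, 0.9))
        assert ratio == np.inf

    def test_empty_region_raises(self):
        aci = self.make_aci(np.ones((10, 10)))
        with pytest.raises(ValueError, match="no pixels"):
            cue_to_noise_ratio(aci, (5000, 6000, 0.1, 0.2),
                               (200, 1000, 0.1, 0.4))


class TestConvergenceCurve:
    def test_final_point_is_one_and_deterministic(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((200, 4, 4))
        r = (rng.random(200) < norm.cdf(X[:, 0, 0])).astype(int)
        n1, c1, _ = convergence_curve(X, r, block=50, estimator="correlation")
        n2, c2, _ = convergence_curve(X, r, block=50, estimator="correlation")
        assert c1[-1] == 1.0
        assert np.array_equal(n1, [50, 100, 150, 200])
        assert np.array_equal(c1, c2)

    def test_block_too_large(self):
        rng = np.random.default_rng(13)
        X, r = null_dataset(rng, n=30)
        with pytest.raises(ValueError):
            convergence_curve(X, r, block=50)

    def test_early_blocks_less_converged(self, planted_session):
        # similarity with the final image grows with the trial count
        _, tensor, r, _ = planted_session
        n_vals, corrs, cnrs = convergence_curve(
            tensor, r, block=400, estimator="correlation",
            cue_region=(380, 650, 0.10, 0.20), noise_region=(380, 650, 0.22, 0.30))
        assert corrs[0] < corrs[-2] <= 1.0
        # cue-to-noise ratio of the planted-template estimate grows too
        from scipy.stats import spearmanr
        rho = spearmanr(n_vals, cnrs).statistic
        assert rho > 0
        assert cnrs[-1] > 1.5


def test_fdr_mask_basic():
    p = np.array([[0.001, 0.2], [0.5, 0.04]])
    mask = fdr_mask(p, alpha=0.05)
    assert mask[0, 0] and not mask[1, 0]
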