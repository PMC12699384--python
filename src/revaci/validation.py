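"""Statistical validation of classification images.

Global checks — within-participant cross-validation (held-out accuracy and
deviance) and between-dataset cross-prediction — and pixel-wise checks via a
response-permutation null.  Convergence diagnostics (similarity of partial
images with the final image, cue-to-noise ratio versus trial count) complete
the module.  Held-out probabilities are clipped at 1e-12 so deviances stay
finite; no multiple-testing correction is applied to pixel-wise statistics
by default (a helper is provided).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimation import (
    ACIResult, ClassificationImageModel, aci_correlation, aci_weighted_sum,
    deviance, glm_fit, make_folds,
)
from .representation import StimulusTensor

__all__ = [
    "ValidationReport",
    "cross_validate",
    "cross_predict",
    "permutation_test",
    "PermutationResult",
    "cue_to_noise_ratio",
    "convergence_curve",
    "fdr_mask",
]


def _fit_estimator(tensor, r, estimator, **kw):
    if isinstance(estimator, str):
        if estimator == "correlation":
            return aci_correlation(tensor, r)
        if estimator == "weighted_sum":
            return aci_weighted_sum(tensor, r)
        penalty = {"glm": "none", "glm_L2": "l2_smooth",
                   "glm_L1_GB": "l1_basis"}.get(estimator)
        if penalty is None:
            raise ValueError(f"unknown estimator {estimator!r}")
        return glm_fit(tensor, r, penalty=penalty, **kw)
    return estimator(tensor, r)


@dataclass
class ValidationReport:
    """Per-fold goodness-of-fit of a classification-image model."""

    per_fold: list                    # (accuracy %, deviance) pairs
    n_folds: int
    mean_accuracy: float = 0.0
    mean_deviance: float = 0.0
    accuracy_ci: tuple = (0.0, 0.0)   # mean +/- 1.96 SE across folds
    deviance_ci: tuple = (0.0, 0.0)
    folds: list = field(default_factory=list, repr=False)

    @classmethod
    def from_folds(cls, per_fold, folds=None):
        acc = np.array([a for a, _ in per_fold])
        dev = np.array([d for _, d in per_fold])
        se_a = acc.std(ddof=1) / np.sqrt(len(acc)) if len(acc) > 1 else 0.0
        se_d = dev.std(ddof=1) / np.sqrt(len(dev)) if len(dev) > 1 else 0.0
        return cls(per_fold=list(per_fold), n_folds=len(per_fold),
                   mean_accuracy=float(acc.mean()),
                   mean_deviance=float(dev.mean()),
                   accuracy_ci=(float(acc.mean() - 1.96 * se_a),
                                float(acc.mean() + 1.96 * se_a)),
                   deviance_ci=(float(dev.mean() - 1.96 * se_d),
                                float(dev.mean() + 1.96 * se_d)),
                   folds=list(folds) if folds is not None else [])


def cross_validate(tensor, r, fit_spec: str | dict = "glm_L1_GB",
                   n_folds: int = 10,
                   rng: np.random.Generator | None = None,
                   folds: list | None = None) -> ValidationReport:
    """K-fold within-dataset cross-validation of a classification image.

    Each fold is held out once; the model refit on the remaining folds
    predicts the held-out responses via the 0.5-threshold rule (accuracy, %)
    and by -2 log-likelihood (deviance).  Folds are disjoint, near-equal and
    stratified on the response so every training set has both classes.
    """
    r = np.asarray(r).astype(int).ravel()
    n = len(r)
    if n_folds > n // 2:
        raise ValueError("need n_folds <= n_trials / 2")
    if rng is None:
        rng = np.random.default_rng(0)
    if folds is None:
        folds = make_folds(n, n_folds, rng, r=r)
    if isinstance(fit_spec, str):
        fit_spec = {"estimator": fit_spec}
    est = fit_spec["estimator"]
    kw = {k: v for k, v in fit_spec.items() if k != "estimator"}

    X = tensor.data if isinstance(tensor, StimulusTensor) else np.asarray(tensor)
    per_fold = []
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        fit = _fit_estimator(X[train], r[train], est, **kw)
        p = fit.predict_proba(X[test])
        acc = 100.0 * float(np.mean((p >= 0.5).astype(int) == r[test]))
        per_fold.append((acc, deviance(r[test], p)))
    return ValidationReport.from_folds(per_fold, folds)


def cross_predict(aci: ACIResult, tensor_b, r_b, folds: list,
                  refit_intercept: bool = False) -> ValidationReport:
    """Goodness of fit of a *fixed* image on another dataset's folds.

    The weights come from ``aci`` unchanged (between-participant
    cross-prediction); the same folds as the within-dataset cross-validation
    are used so the metrics are directly comparable.  ``refit_intercept``
    optionally re-estimates only the intercept on each training fold.
    """
    from scipy.optimize import minimize_scalar
    from scipy.stats import norm

    r_b = np.asarray(r_b).astype(int).ravel()
    X = tensor_b.data if isinstance(tensor_b, StimulusTensor) else np.asarray(tensor_b)
    if X.shape[1:] != aci.weights.shape:
        raise ValueError(f"representation dims {X.shape[1:]} do not match "
                         f"the image {aci.weights.shape}")
    w = aci.weights.ravel()
    per_fold = []
    for test in folds:
        c = aci.intercept
        if refit_intercept:
            train = np.setdiff1d(np.arange(len(r_b)), test)
            eta_t = X[train].reshape(len(train), -1) @ w

            def nll(cc):
                p = np.clip(norm.cdf(eta_t + cc), 1e-12, 1 - 1e-12)
                return -np.sum(r_b[train] * np.log(p)
                               + (1 - r_b[train]) * np.log(1 - p))

            c = float(minimize_scalar(nll).x)
        eta = X[test].reshape(len(test), -1) @ w + c
        p = norm.cdf(eta)
        acc = 100.0 * float(np.mean((p >= 0.5).astype(int) == r_b[test]))
        per_fold.append((acc, deviance(r_b[test], p)))
    return ValidationReport.from_folds(per_fold, folds)


@dataclass
class PermutationResult:
    """Null distribution of images under response permutation."""

    null_weights: np.ndarray          # n_perm x n_f x n_t
    lo: np.ndarray                    # per-pixel 5th percentile
    hi: np.ndarray                    # per-pixel 95th percentile
    mask: np.ndarray                  # observed weight outside [lo, hi]
    observed: ACIResult
    n_perm: int

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.mask))


def permutation_test(tensor, r, estimator: str = "correlation",
                     n_perm: int = 100,
                     rng: np.random.Generator | None = None,
                     observed: ACIResult | None = None,
                     percentiles=(5.0, 95.0), **est_kw) -> PermutationResult:
    """Pixel-wise significance via a response-permutation null.

    ``n_perm`` random permutations of the response vector (class counts
    preserved by construction) each yield a null image; pixels of the
    observed image outside the per-pixel [5th, 95th] null percentiles are
    flagged significant.  GLM-based estimators work but are costly.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_perm < 20:
        warnings.warn("n_perm < 20: percentile estimates will be unstable",
                      RuntimeWarning)
    r = np.asarray(r).astype(int).ravel()
    if observed is None:
        observed = _fit_estimator(tensor, r, estimator, **est_kw)
    X = tensor.data if isinstance(tensor, StimulusTensor) else np.asarray(tensor)
    null = np.empty((n_perm,) + observed.weights.shape)
    for b in range(n_perm):
        r_perm = rng.permutation(r)
        null[b] = _fit_estimator(X, r_perm, estimator, **est_kw).weights
    # outward order-statistic convention: with n_perm null draws this puts
    # the interval's nominal coverage at the stated level (interpolated
    # percentiles under-cover slightly at small n_perm)
    lo = np.percentile(null, percentiles[0], axis=0, method="lower")
    hi = np.percentile(null, percentiles[1], axis=0, method="higher")
    mask = (observed.weights < lo) | (observed.weights > hi)
    return PermutationResult(null, lo, hi, mask, observed, n_perm)


def cue_to_noise_ratio(aci, cue_region, noise_region) -> float:
    """Mean squared weight in the cue region over that in a null region.

    Regions are ``(f_lo, f_hi, t_lo, t_hi)`` in axis units.  A uniform
    |weight| image gives exactly 1; the ratio is invariant to rescaling the
    image.  A zero denominator returns +inf with a warning.
    """
    w = aci.weights if isinstance(aci, ACIResult) else np.asarray(aci)
    if isinstance(aci, ACIResult):
        f_axis, t_axis = np.asarray(aci.freq_axis), np.asarray(aci.time_axis)
    else:
        f_axis = np.arange(w.shape[0])
        t_axis = np.arange(w.shape[1])

    def region_mean_sq(region):
        f_lo, f_hi, t_lo, t_hi = region
        fi = (f_axis >= f_lo) & (f_axis <= f_hi)
        ti = (t_axis >= t_lo) & (t_axis <= t_hi)
        if not fi.any() or not ti.any():
            raise ValueError(f"region {region} selects no pixels")
        return float(np.mean(w[np.ix_(fi, ti)] ** 2))

    num = region_mean_sq(cue_region)
    den = region_mean_sq(noise_region)
    if den == 0:
        warnings.warn("noise region has zero weights; ratio is infinite",
                      RuntimeWarning)
        return float("inf")
    return num / den


def convergence_curve(tensor, r, block: int = 400,
                      estimator: str = "correlation",
                      cue_region=None, noise_region=None, **est_kw):
    """Stability of the image as trials accumulate.

    Fits a partial image on the first ``k * block`` trials for each k,
    returning ``(n_values, correlation_with_final, cue_to_noise_per_n)``
    (the last entry of the correlation track is exactly 1, and the
    cue-to-noise track is None when no regions are given).
    """
    r = np.asarray(r).astype(int).ravel()
    n = len(r)
    if block > n:
        raise ValueError("block size exceeds the number of trials")
    X = tensor.data if isinstance(tensor, StimulusTensor) else np.asarray(tensor)
    ks = list(range(block, n + 1, block))
    if ks[-1] != n:
        ks.append(n)
    final = _fit_estimator(X, r, estimator, **est_kw)
    fw = final.weights.ravel()
    n_values, corrs, cnrs = [], [], []
    for m in ks:
        part = _fit_estimator(X[:m], r[:m], estimator, **est_kw)
        pw = part.weights.ravel()
        denom = np.linalg.norm(pw - pw.mean()) * np.linalg.norm(fw - fw.mean())
        corr = 1.0 if m == n else (
            float((pw - pw.mean()) @ (fw - fw.mean()) / denom) if denom > 0 else 0.0)
        n_values.append(m)
        corrs.append(corr)
        if cue_region is not None and noise_region is not None:
            part_res = ACIResult(part.weights, part.intercept, part.method,
                                 final.freq_axis, final.time_axis)
            if isinstance(tensor, StimulusTensor):
                part_res.freq_axis = tensor.freq_axis
                part_res.time_axis = tensor.time_axis
            cnrs.append(cue_to_noise_ratio(part_res, cue_region, noise_region))
    return np.array(n_values), np.array(corrs), \
        (np.array(cnrs) if cnrs else None)


def fdr_mask(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg FDR mask over a p-value map (helper, off by default)."""
    p = np.asarray(pvals).ravel()
    order = np.argsort(p)
    m = p.size
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if passed.any():
        k = np.max(np.flatnonzero(passed))
        mask[order[: k + 1]] = True
    return mask.reshape(np.asarray(pvals).shape)
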