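"""Classification-image estimation: correlation, weighted sum, probit GLMs.

The central object is :class:`ClassificationImageModel`, built from a
trials x frequency x time noise tensor and a binary response vector, whose
``fit`` method returns an :class:`ACIResult` carrying the weight matrix (the
classification image), the intercept, the regularization path and
diagnostics.  Five estimators are available:

``correlation``
    per-pixel Pearson correlation between noise and responses;
``weighted_sum``
    mean noise for "response 2" minus mean noise for "response 1";
``glm``
    maximum-likelihood probit regression, P(r=1) = Phi(N.w + c);
``glm_L2``
    probit regression with a smoothness penalty (squared first differences
    between neighboring pixels along both axes);
``glm_L1_GB``
    probit regression with a lasso penalty on a Gaussian-pyramid basis, the
    image being the basis expansion of the sparse coefficients.

Sign convention (uniform across estimators): responses are coded r in {0,1}
with 1 = "response 2", and positive weights mark noise energy that pushes
the listener toward "response 2".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .representation import StimulusTensor, zscore_pixels

__all__ = [
    "ACIResult",
    "GaussianBasis",
    "build_gaussian_basis",
    "ClassificationImageModel",
    "aci_correlation",
    "aci_weighted_sum",
    "glm_fit",
    "search_lambda",
    "make_folds",
    "deviance",
    "ConvergenceError",
]

EPS_PROB = 1e-12
METHODS = ("correlation", "weighted_sum", "glm", "glm_L2", "glm_L1_GB")


class ConvergenceError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Results object
# --------------------------------------------------------------------------

@dataclass
class ACIResult:
    """Fitted classification image and its diagnostics.

    ``weights`` is the n_f x n_t perceptual-weight matrix; positive entries
    favor "response 2".  For penalized fits ``lambda_`` is the value used and
    ``lambda_path`` the cross-validation trace as (lambda, CV deviance,
    CV accuracy %) triples sorted by lambda.
    """

    weights: np.ndarray
    intercept: float
    method: str
    freq_axis: np.ndarray
    time_axis: np.ndarray
    lambda_: float | None = None
    lambda_path: list = field(default_factory=list)
    per_pixel_stats: dict = field(default_factory=dict)
    coef_basis: np.ndarray | None = None
    basis: "GaussianBasis | None" = None
    converged: bool = True
    n_trials: int = 0
    sign_convention: str = "r=1 codes 'response 2'; positive weight favors it"
    validation: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.weights.shape

    def linear_predictor(self, tensor) -> np.ndarray:
        X = tensor.as_matrix() if isinstance(tensor, StimulusTensor) \
            else np.asarray(tensor).reshape(len(tensor), -1)
        return X @ self.weights.ravel() + self.intercept

    def predict_proba(self, tensor) -> np.ndarray:
        """P(r = 1), i.e. probability of 'response 2', per trial."""
        return stats.norm.cdf(self.linear_predictor(tensor))

    def predict(self, tensor) -> np.ndarray:
        """Hard response prediction in {0, 1} via the 0.5-threshold rule."""
        return (self.predict_proba(tensor) >= 0.5).astype(int)

    def deviance(self, tensor, r) -> float:
        return deviance(np.asarray(r), self.predict_proba(tensor))

    # validation conveniences (delegate to the validation module)
    def permutation_test(self, tensor, r, n_perm=100, rng=None, **kw):
        from .validation import permutation_test
        return permutation_test(tensor, r, estimator=self.method,
                                n_perm=n_perm, rng=rng, observed=self, **kw)

    def cue_to_noise_ratio(self, cue_region, noise_region):
        from .validation import cue_to_noise_ratio
        return cue_to_noise_ratio(self, cue_region, noise_region)

    def summary(self) -> str:
        n_f, n_t = self.weights.shape
        lines = [
            "Classification image (ACI) fit",
            "=" * 46,
            f"method:        {self.method}",
            f"image shape:   {n_f} x {n_t} (freq x time)",
            f"trials:        {self.n_trials}",
            f"intercept c:   {self.intercept: .4f}",
            f"max |weight|:  {np.max(np.abs(self.weights)):.4g}",
            f"coding:        {self.sign_convention}",
        ]
        if self.lambda_ is not None:
            lines.append(f"lambda:        {self.lambda_:.4g}")
        if self.lambda_path:
            best = min(self.lambda_path, key=lambda t: (t[1], t[0]))
            lines.append(f"CV deviance:   {best[1]:.2f} "
                         f"(accuracy {best[2]:.1f}%) at lambda={best[0]:.4g}")
        if not self.converged:
            lines.append("WARNING: fit did not fully converge")
        return "\n".join(lines)

    def plot(self, ax=None, **kw):
        """Image plot of the weights (red = favors response 2)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        v = np.max(np.abs(self.weights)) or 1.0
        m = ax.pcolormesh(self.time_axis, self.freq_axis, self.weights,
                          cmap="RdBu_r", vmin=-v, vmax=v, **kw)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        ax.figure.colorbar(m, ax=ax, label="perceptual weight")
        return ax


# --------------------------------------------------------------------------
# Helpers
# --------------------------------------------------------------------------

def _as_Xr(tensor, r):
    if isinstance(tensor, StimulusTensor):
        X = tensor.as_matrix()
        axes = (tensor.freq_axis, tensor.time_axis, tensor.data.shape[1:])
    else:
        arr = np.asarray(tensor, dtype=float)
        if arr.ndim == 3:
            X = arr.reshape(arr.shape[0], -1)
            axes = (np.arange(arr.shape[1]), np.arange(arr.shape[2]), arr.shape[1:])
        else:
            X = arr
            axes = (np.arange(arr.shape[1]), np.arange(1), (arr.shape[1], 1))
    r = np.asarray(r).astype(float).ravel()
    if len(r) != X.shape[0]:
        raise ValueError("tensor and responses are not aligned")
    if not np.all(np.isin(r, (0.0, 1.0))):
        raise ValueError("responses must be binary 0/1 (1 = 'response 2')")
    return X, r, axes


def _base_rate_intercept(r) -> float:
    return float(stats.norm.ppf(np.clip(np.mean(r), EPS_PROB, 1 - EPS_PROB)))


def deviance(r, p) -> float:
    """-2 log-likelihood of binary responses under probabilities p."""
    p = np.clip(p, EPS_PROB, 1 - EPS_PROB)
    return float(-2.0 * np.sum(r * np.log(p) + (1 - r) * np.log(1 - p)))


def make_folds(n: int, n_folds: int, rng: np.random.Generator,
               r=None) -> list[np.ndarray]:
    """Seeded random partition into n_folds near-equal folds.

    When ``r`` is given the partition is stratified on the response class, so
    every training set contains both classes.  The same fold assignment is
    reused between hyperparameter search and validation for comparability.
    """
    if n_folds < 2 or n_folds > n:
        raise ValueError("need 2 <= n_folds <= n")
    assign = np.empty(n, dtype=int)
    if r is None:
        perm = rng.permutation(n)
        assign[perm] = np.arange(n) % n_folds
    else:
        r = np.asarray(r).ravel()
        for cls in np.unique(r):
            pos = np.flatnonzero(r == cls)
            perm = rng.permutation(pos.size)
            assign[pos[perm]] = np.arange(pos.size) % n_folds
    return [np.flatnonzero(assign == k) for k in range(n_folds)]


# --------------------------------------------------------------------------
# Correlation & weighted sum
# --------------------------------------------------------------------------

def aci_correlation(tensor, r) -> ACIResult:
    """Per-pixel Pearson correlation between noise values and responses."""
    X, r, (f_axis, t_axis, shape) = _as_Xr(tensor, r)
    n = X.shape[0]
    if n < 3:
        raise ValueError("correlation needs at least 3 trials")
    if r.min() == r.max():
        raise ValueError("responses are all identical")
    Xc = X - X.mean(axis=0)
    rc = r - r.mean()
    sx = np.sqrt(np.sum(Xc**2, axis=0))
    sr = np.sqrt(np.sum(rc**2))
    const = sx == 0
    denom = np.where(const, 1.0, sx * sr)
    w = (Xc.T @ rc) / denom
    w[const] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = w * np.sqrt((n - 2) / np.maximum(1 - w**2, EPS_PROB))
    pvals = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    # intercept on the probit scale so predict_proba honors the base rate
    return ACIResult(w.reshape(shape), intercept=_base_rate_intercept(r),
                     method="correlation", freq_axis=f_axis, time_axis=t_axis,
                     per_pixel_stats={"t": tstat.reshape(shape),
                                      "p": pvals.reshape(shape),
                                      "const_mask": const.reshape(shape)},
                     n_trials=n)


def aci_weighted_sum(tensor, r) -> ACIResult:
    """Mean noise given 'response 2' minus mean noise given 'response 1'."""
    X, r, (f_axis, t_axis, shape) = _as_Xr(tensor, r)
    if r.min() == r.max():
        raise ValueError("both response classes must be present")
    w = X[r == 1].mean(axis=0) - X[r == 0].mean(axis=0)
    return ACIResult(w.reshape(shape), intercept=_base_rate_intercept(r),
                     method="weighted_sum", freq_axis=f_axis, time_axis=t_axis,
                     n_trials=X.shape[0])


# --------------------------------------------------------------------------
# Gaussian-pyramid basis
# --------------------------------------------------------------------------

@dataclass
class GaussianBasis:
    """Multi-scale dictionary of 2-D Gaussian bumps on the pixel grid.

    Level ``l`` places unit-peak Gaussians with sigma ``2**(l-1)`` bins on a
    grid of spacing ``2**(l-1)``, so element counts shrink as levels coarsen.
    ``design`` maps coefficient space to pixel space (one column per element,
    each column nonnegative with max 1).
    """

    elements: list            # (cf, ct, sigma_f, sigma_t, level)
    design: np.ndarray        # (n_f * n_t) x n_elements
    shape: tuple[int, int]
    level_min: int
    level_max: int


def build_gaussian_basis(n_f: int, n_t: int, level_min: int = 2,
                         level_max: int = 5) -> GaussianBasis:
    if level_min > level_max:
        raise ValueError("level_min must be <= level_max")
    if n_f < 4 or n_t < 4:
        raise ValueError("image must be at least 4 x 4 pixels")
    ff, tt = np.meshgrid(np.arange(n_f), np.arange(n_t), indexing="ij")
    cols, elements = [], []
    for level in range(level_min, level_max + 1):
        s = 2 ** (level - 1)
        centers_f = np.arange(0, n_f, s)
        centers_t = np.arange(0, n_t, s)
        for cf in centers_f:
            for ct in centers_t:
                g = np.exp(-0.5 * (((ff - cf) / s) ** 2 + ((tt - ct) / s) ** 2))
                cols.append(g.ravel())
                elements.append((int(cf), int(ct), float(s), float(s), level))
    design = np.column_stack(cols)
    return GaussianBasis(elements, design, (n_f, n_t), level_min, level_max)


# --------------------------------------------------------------------------
# Probit GLM fitting
# --------------------------------------------------------------------------

def _probit_nll_grad(eta, r):
    """Negative log-likelihood and its derivative with respect to eta."""
    p = np.clip(stats.norm.cdf(eta), EPS_PROB, 1 - EPS_PROB)
    nll = -np.sum(r * np.log(p) + (1 - r) * np.log(1 - p))
    phi = stats.norm.pdf(eta)
    grad = phi * (p - r) / (p * (1 - p))
    return nll, grad


def _irls_probit(Z, r, penalty_matrix=None, lam=0.0, max_iter=200, tol=1e-9):
    """Newton/IRLS for probit regression with optional quadratic penalty.

    ``Z`` includes the intercept column (last); the penalty matrix never
    touches the intercept.  Returns (coef, converged, trace).
    """
    n, m = Z.shape
    beta = np.zeros(m)
    trace = []
    sep_warned = False
    for it in range(max_iter):
        eta = Z @ beta
        p = np.clip(stats.norm.cdf(eta), EPS_PROB, 1 - EPS_PROB)
        phi = stats.norm.pdf(eta)
        # working weights / response for the probit log-likelihood
        grad_eta = phi * (p - r) / (p * (1 - p))
        w_work = phi**2 / (p * (1 - p))
        g = Z.T @ grad_eta
        H = (Z * w_work[:, None]).T @ Z
        if penalty_matrix is not None and lam > 0:
            g = g + 2 * lam * (penalty_matrix @ beta)
            H = H + 2 * lam * penalty_matrix
        H.flat[:: m + 1] += 1e-10
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # backtracking on the penalized objective
        obj0, _ = _probit_nll_grad(eta, r)
        if penalty_matrix is not None and lam > 0:
            obj0 += lam * float(beta @ (penalty_matrix @ beta))
        t = 1.0
        for _ in range(30):
            cand = beta - t * step
            obj, _ = _probit_nll_grad(Z @ cand, r)
            if penalty_matrix is not None and lam > 0:
                obj += lam * float(cand @ (penalty_matrix @ cand))
            if obj <= obj0 + 1e-12:
                break
            t *= 0.5
        beta = cand
        trace.append(obj)
        if np.max(np.abs(Z @ beta)) > 25 and not sep_warned:
            warnings.warn(
                "probit fit drifting toward perfect separation; consider a "
                "penalized fit (glm_L2 or glm_L1_GB)", RuntimeWarning)
            sep_warned = True
            return beta, False, trace
        if it > 0 and abs(trace[-2] - trace[-1]) <= tol * (abs(trace[-2]) + 1):
            return beta, True, trace
    raise ConvergenceError(
        f"IRLS did not converge in {max_iter} iterations; objective trace "
        f"tail: {[round(v, 6) for v in trace[-5:]]}")


def _smoothness_penalty(n_f, n_t):
    """Sum-of-squared first differences operator (both axes) as D'D."""
    npx = n_f * n_t
    rows, cols, vals = [], [], []
    k = 0
    idx = np.arange(npx).reshape(n_f, n_t)
    for (a, b) in [(idx[:-1, :].ravel(), idx[1:, :].ravel()),
                   (idx[:, :-1].ravel(), idx[:, 1:].ravel())]:
        for i, j in zip(a, b):
            rows += [k, k]
            cols += [i, j]
            vals += [1.0, -1.0]
            k += 1
    from scipy.sparse import coo_matrix
    D = coo_matrix((vals, (rows, cols)), shape=(k, npx)).tocsr()
    return (D.T @ D).toarray()


def _fista_l1(Z, r, lam, beta0=None, max_iter=10_000, tol=1e-6):
    """FISTA for probit NLL + lam * ||beta[:-1]||_1 (intercept unpenalized)."""
    n, m = Z.shape
    beta = np.zeros(m) if beta0 is None else beta0.copy()
    y = beta.copy()
    t_mom = 1.0
    # Lipschitz bound: probit NLL curvature wrt eta is < 1.1
    L = 1.1 * np.linalg.norm(Z, 2) ** 2
    obj_prev = np.inf
    objs = []
    for it in range(max_iter):
        nll, g_eta = _probit_nll_grad(Z @ y, r)
        grad = Z.T @ g_eta
        b_new = y - grad / L
        b_new[:-1] = np.sign(b_new[:-1]) * np.maximum(np.abs(b_new[:-1]) - lam / L, 0.0)
        # the global step 1/L is far too small for the intercept coordinate;
        # refine it with a couple of exact 1-D Newton steps
        eta_fixed = Z[:, :-1] @ b_new[:-1]
        for _ in range(2):
            eta = eta_fixed + b_new[-1]
            p = np.clip(stats.norm.cdf(eta), EPS_PROB, 1 - EPS_PROB)
            phi = stats.norm.pdf(eta)
            g_c = np.sum(phi * (p - r) / (p * (1 - p)))
            h_c = np.sum(phi**2 / (p * (1 - p)))
            if h_c > 0:
                b_new[-1] -= g_c / h_c
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t_mom**2))
        y = b_new + ((t_mom - 1) / t_new) * (b_new - beta)
        beta, t_mom = b_new, t_new
        if it % 10 == 0 or it == max_iter - 1:
            nll_b, _ = _probit_nll_grad(Z @ beta, r)
            obj = nll_b + lam * np.sum(np.abs(beta[:-1]))
            objs.append(obj)
            if obj > obj_prev + 1e-10:   # momentum overshoot: restart
                y = beta.copy()
                t_mom = 1.0
            elif abs(obj_prev - obj) <= tol * (abs(obj) + 1):
                return beta, True, objs
            obj_prev = min(obj_prev, obj)
    return beta, False, objs


def glm_fit(tensor, r, penalty: str = "none", lam: float = 0.0,
            basis: GaussianBasis | None = None, **solver_kw) -> ACIResult:
    """Probit-GLM classification image, optionally penalized.

    ``penalty='none'`` gives the maximum-likelihood fit; ``'l2_smooth'``
    adds ``lam`` times the sum of squared first differences between
    neighboring pixels; ``'l1_basis'`` fits sparse coefficients on a
    :class:`GaussianBasis` (built automatically if not supplied) under an L1
    penalty, the image being their basis expansion.  The intercept is never
    penalized.
    """
    X, r, (f_axis, t_axis, shape) = _as_Xr(tensor, r)
    if r.min() == r.max():
        raise ValueError("both response classes must be present for a GLM fit")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, npx = X.shape
    ones = np.ones((n, 1))

    if penalty == "none":
        Z = np.hstack([X, ones])
        beta, conv, trace = _irls_probit(Z, r, **solver_kw)
        w, c = beta[:-1], float(beta[-1])
        res = ACIResult(w.reshape(shape), c, "glm", f_axis, t_axis,
                        converged=conv, n_trials=n)
        if npx <= 512 and conv:
            res.per_pixel_stats = _glm_pixel_stats(Z, beta, r, shape)
        return res

    # the penalty weight is per trial (it balances the *mean* log-likelihood),
    # so lambda values are comparable across dataset sizes
    lam_eff = lam * n

    if penalty == "l2_smooth":
        P = np.zeros((npx + 1, npx + 1))
        P[:npx, :npx] = _smoothness_penalty(*shape)
        Z = np.hstack([X, ones])
        beta, conv, _ = _irls_probit(Z, r, penalty_matrix=P, lam=lam_eff, **solver_kw)
        return ACIResult(beta[:-1].reshape(shape), float(beta[-1]), "glm_L2",
                         f_axis, t_axis, lambda_=lam, converged=conv, n_trials=n)

    if penalty == "l1_basis":
        if basis is None:
            basis = build_gaussian_basis(*shape)
        Z = np.hstack([X @ basis.design, ones])
        beta0 = solver_kw.pop("beta0", None)
        beta, conv, _ = _fista_l1(Z, r, lam_eff, beta0=beta0, **solver_kw)
        coef, c = beta[:-1], float(beta[-1])
        w = basis.design @ coef
        return ACIResult(w.reshape(shape), c, "glm_L1_GB", f_axis, t_axis,
                         lambda_=lam, coef_basis=beta, basis=basis,
                         converged=conv, n_trials=n)

    raise ValueError(f"unknown penalty {penalty!r}")


def _glm_pixel_stats(Z, beta, r, shape):
    eta = Z @ beta
    p = np.clip(stats.norm.cdf(eta), EPS_PROB, 1 - EPS_PROB)
    phi = stats.norm.pdf(eta)
    w_work = phi**2 / (p * (1 - p))
    H = (Z * w_work[:, None]).T @ Z
    try:
        cov = np.linalg.inv(H + 1e-10 * np.eye(H.shape[0]))
    except np.linalg.LinAlgError:
        return {}
    se = np.sqrt(np.maximum(np.diag(cov)[:-1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta[:-1] / se, 0.0)
    return {"z": z.reshape(shape),
            "p": (2 * stats.norm.sf(np.abs(z))).reshape(shape),
            "se": se.reshape(shape)}


# --------------------------------------------------------------------------
# Hyperparameter search
# --------------------------------------------------------------------------

def search_lambda(tensor, r, penalty: str, lambda0: float = 5.0,
                  factor: float = 5.0, maxiter: int = 30,
                  precision: float = 0.05, n_folds: int = 10,
                  rng: np.random.Generator | None = None,
                  basis: GaussianBasis | None = None,
                  folds: list | None = None,
                  solver_kw: dict | None = None):
    """Cross-validated search for the penalty weight lambda.

    Walks a geometric grid descending from ``lambda0`` by ``factor``,
    scoring each value by 10-fold cross-validated deviance (folds are
    seeded, stratified, and shared with downstream validation), then refines
    geometrically around the running minimum until the relative change in CV
    deviance drops below ``precision`` or ``maxiter`` values have been
    fitted.  Returns ``(lambda*, path)`` with the path sorted by lambda and
    ties resolved toward the smaller lambda.
    """
    if penalty == "none":
        raise ValueError("search_lambda requires a penalized fit")
    X, r, _ = _as_Xr(tensor, r)
    if rng is None:
        rng = np.random.default_rng(0)
    if folds is None:
        folds = make_folds(len(r), n_folds, rng, r=r)
    # CV scoring fits are cheaper than the final fit at lambda*
    solver_kw = {**({"max_iter": 3000, "tol": 1e-5} if penalty == "l1_basis"
                    else {}), **(solver_kw or {})}
    if penalty == "l1_basis" and basis is None:
        if isinstance(tensor, StimulusTensor):
            basis = build_gaussian_basis(*tensor.data.shape[1:])
        else:
            arr = np.asarray(tensor)
            basis = build_gaussian_basis(*arr.shape[1:])

    warm: dict[int, np.ndarray] = {}

    def cv_score(lam):
        devs, accs = [], []
        for k, test in enumerate(folds):
            train = np.setdiff1d(np.arange(len(r)), test, assume_unique=False)
            kw = dict(solver_kw)
            if penalty == "l1_basis" and k in warm:
                kw["beta0"] = warm[k]
            fit = glm_fit(X[train].reshape(len(train), *_img_shape(tensor)),
                          r[train], penalty=penalty, lam=lam, basis=basis, **kw)
            if penalty == "l1_basis":
                warm[k] = fit.coef_basis
            Xt = X[test].reshape(len(test), *_img_shape(tensor))
            p = fit.predict_proba(Xt)
            devs.append(deviance(r[test], p))
            accs.append(100.0 * np.mean((p >= 0.5).astype(int) == r[test]))
        return float(np.mean(devs)), float(np.mean(accs))

    path = []  # (lam, cv_dev, cv_acc)

    def evaluate(lam):
        dev, acc = cv_score(lam)
        path.append((lam, dev, acc))
        return dev

    # coarse descending geometric grid: walk down until the CV deviance has
    # clearly turned back up (past the minimum by the precision margin)
    lam = float(lambda0)
    evaluate(lam)
    while len(path) < maxiter:
        lam /= factor
        dev = evaluate(lam)
        best = min(p[1] for p in path)
        if dev > best * (1.0 + precision):
            break
        if lam < lambda0 / factor**8:
            break

    # geometric refinement around the minimum
    while len(path) < maxiter:
        path.sort(key=lambda t: t[0])
        lams = [p[0] for p in path]
        devs = [p[1] for p in path]
        i = int(np.argmin(devs))
        candidates = []
        if i > 0:
            candidates.append(np.sqrt(lams[i] * lams[i - 1]))
        if i < len(lams) - 1:
            candidates.append(np.sqrt(lams[i] * lams[i + 1]))
        if not candidates:
            break
        before = min(devs)
        improved = False
        for cand in candidates:
            if len(path) >= maxiter:
                break
            dev = evaluate(cand)
            if dev < before - precision * max(abs(before), 1e-12):
                improved = True
        if not improved:
            break

    if len(path) < 2:
        raise ValueError("fewer than 2 lambda values evaluated")
    path.sort(key=lambda t: t[0])
    best_dev = min(p[1] for p in path)
    lam_star = min(p[0] for p in path if p[1] == best_dev)
    return lam_star, path


def _img_shape(tensor):
    if isinstance(tensor, StimulusTensor):
        return tensor.data.shape[1:]
    arr = np.asarray(tensor)
    return arr.shape[1:] if arr.ndim == 3 else (arr.shape[1], 1)


# --------------------------------------------------------------------------
# Model front door
# --------------------------------------------------------------------------

class ClassificationImageModel:
    """Reverse-correlation model linking noise fluctuations to responses.

    Parameters
    ----------
    tensor : StimulusTensor or ndarray
        trials x n_f x n_t noise representations (presentation order).
    responses : array-like of {0, 1}
        Binary responses, 1 = "response 2".
    zscore : bool
        Standardize each pixel across trials before fitting (recommended;
        makes the correlation and weighted-sum images proportional and puts
        GLM weights on a common unitless scale).
    """

    def __init__(self, tensor, responses, zscore: bool = True):
        if not isinstance(tensor, StimulusTensor):
            arr = np.asarray(tensor, dtype=float)
            if arr.ndim != 3:
                raise ValueError("tensor must be trials x n_f x n_t")
            tensor = StimulusTensor(arr, np.arange(arr.shape[1]),
                                    np.arange(arr.shape[2]))
        if zscore and not tensor.zscored:
            tensor = zscore_pixels(tensor)
        self.tensor = tensor
        self.responses = np.asarray(responses).astype(int).ravel()
        if len(self.responses) != tensor.n_trials:
            raise ValueError("responses and tensor are not aligned")

    @classmethod
    def from_session(cls, session, repr_spec=None, criteria=None,
                     zscore: bool = True, source: str = "noise_alone"):
        """Build the model from a recorded session (trial selection included)."""
        from .preprocess import select_trials
        from .representation import dataload
        idx = select_trials(session, criteria)
        tensor = dataload(session, repr_spec, source=source).subset(idx)
        r = session.responses01[idx]
        return cls(tensor, r, zscore=zscore)

    def fit(self, method: str = "correlation", lam: float | None = None,
            n_folds: int = 10, seed: int = 0, basis=None,
            search_kw: dict | None = None, **solver_kw) -> ACIResult:
        """Estimate the classification image.

        For the penalized methods, ``lam=None`` triggers the cross-validated
        lambda search; the winning lambda and the full (lambda, CV deviance,
        CV accuracy) path are attached to the result.
        """
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        t, r = self.tensor, self.responses
        if method == "correlation":
            return aci_correlation(t, r)
        if method == "weighted_sum":
            return aci_weighted_sum(t, r)
        penalty = {"glm": "none", "glm_L2": "l2_smooth",
                   "glm_L1_GB": "l1_basis"}[method]
        path = []
        if penalty != "none" and lam is None:
            rng = np.random.default_rng(seed)
            lam, path = search_lambda(t, r, penalty, n_folds=n_folds, rng=rng,
                                      basis=basis, solver_kw=solver_kw,
                                      **(search_kw or {}))
        res = glm_fit(t, r, penalty=penalty, lam=lam or 0.0, basis=basis,
                      **solver_kw)
        res.lambda_path = path
        return res
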