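"""Generalized least squares under the combined phylogenetic-spatial variance model.

For a fixed variance matrix V the ML solution is closed-form:

    beta_hat  = (X' V^-1 X)^-1 X' V^-1 y
    sigma2_ml = (y - X beta_hat)' V^-1 (y - X beta_hat) / n
    loglik    = -0.5 * [n log(2 pi sigma2_ml) + log|V| + n]

The dependence parameters (lambda, phi) enter only through V, so they are
estimated by maximizing this profile likelihood over the unit square with a
coarse grid seed followed by bounded quasi-Newton refinement. ML (not REML) is
used throughout because AICc comparisons across different fixed-effects
structures require it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from pglspatial.covariance import CovarianceSet, VarianceParams, combined_variance, lambda_transform

__all__ = [
    "GLSFit",
    "SignalResult",
    "DependenceTests",
    "VarianceCache",
    "gls_fit_fixed",
    "fit_pgls_spatial",
    "sweep_profile_grid",
    "dependence_tests",
    "pagel_lambda_signal",
    "gls_r_squared",
]

GRID_POINTS = 11          # coarse seed grid per free dimension
N_STARTS = 3              # refinement starts from the best grid points
OBJ_TOL = 1e-8            # convergence tolerance on the (negative) log-likelihood
BOUNDARY_SNAP = 1e-6      # estimates this close to 0/1 are reported exactly at the bound
_DEGENERATE_RSS = 1e-12   # relative threshold for a perfect fit


@dataclass
class GLSFit:
    """One fitted GLS regression: coefficients, scale, likelihood and AICc."""

    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    loglik: float
    n: int
    k: int
    aicc: float
    params: VarianceParams | None = None
    r2: float | None = None
    terms: list[str] = field(default_factory=list)
    degenerate: bool = False

    def coef_table(self):
        import pandas as pd

        ci_lo = self.beta - 1.96 * self.se
        ci_hi = self.beta + 1.96 * self.se
        terms = self.terms or [f"x{i}" for i in range(len(self.beta))]
        return pd.DataFrame(
            {"term": terms, "beta": self.beta, "se": self.se, "ci_lo": ci_lo, "ci_hi": ci_hi}
        )


@dataclass
class SignalResult:
    """Pagel's-lambda phylogenetic signal estimate with its likelihood-ratio test."""

    lam_hat: float
    loglik_hat: float
    p_value: float
    n: int


@dataclass
class DependenceTests:
    """Likelihood-ratio tests for the phylogenetic and spatial variance components."""

    p_lambda: float
    p_phi: float
    fits: dict  # mode -> GLSFit for {both, lambda_only, phi_only, neither}


def _aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _chol_logdet(V: np.ndarray):
    """Lower Cholesky factor and log-determinant; tiny ridge retry for PSD edge cases."""
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        ridge = 1e-10 * float(np.mean(np.diag(V)))
        try:
            L = np.linalg.cholesky(V + ridge * np.eye(V.shape[0]))
        except np.linalg.LinAlgError:
            return None, None
    return L, 2.0 * float(np.sum(np.log(np.diag(L))))


def _whitened_ml(Xw: np.ndarray, yw: np.ndarray, logdet: float):
    """ML quantities from whitened data. Returns (beta, rss, sigma2, loglik, XtXinv)."""
    n, p = Xw.shape
    q, r = np.linalg.qr(Xw)
    rdiag = np.abs(np.diag(r))
    if p and rdiag.min() < 1e-10 * max(rdiag.max(), 1.0):
        bad = [int(i) for i in np.where(rdiag < 1e-10 * max(rdiag.max(), 1.0))[0]]
        raise np.linalg.LinAlgError(f"design matrix is rank deficient (columns {bad})")
    beta = solve_triangular(r, q.T @ yw, lower=False)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    yscale = max(float(yw @ yw), 1.0)
    if rss < _DEGENERATE_RSS * yscale:
        return beta, rss, sigma2, np.inf, None
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    rinv = solve_triangular(r, np.eye(p), lower=False)
    xtx_inv = rinv @ rinv.T
    return beta, rss, sigma2, loglik, xtx_inv


class VarianceCache:
    """Bounded LRU cache of Cholesky factors of V(lambda, phi) for one CovarianceSet.

    All-subsets model averaging evaluates thousands of fits at a shared grid of
    (lambda, phi) values; factoring V once per grid point and whitening the full
    design once per factor makes the enumeration cheap. Whitened arrays are
    cached by object identity. The LRU bound keeps the hot seed-grid entries
    resident while the one-off points visited by the refinement stage are
    evicted.
    """

    def __init__(self, cov: CovarianceSet, max_entries: int = 512):
        from collections import OrderedDict

        self.cov = cov
        self.max_entries = max_entries
        self._factors: "OrderedDict" = OrderedDict()
        self._whitened: "OrderedDict" = OrderedDict()

    @staticmethod
    def _lru_get(store, key):
        if key in store:
            store.move_to_end(key)
            return store[key]
        return None

    def _lru_put(self, store, key, value):
        store[key] = value
        store.move_to_end(key)
        if len(store) > self.max_entries:
            store.popitem(last=False)

    def factor(self, lam: float, phi: float):
        key = (round(float(lam), 12), round(float(phi), 12))
        hit = self._lru_get(self._factors, key)
        if hit is None:
            V = combined_variance(self.cov, VarianceParams(lam=key[0], phi=key[1]))
            hit = _chol_logdet(V)
            self._lru_put(self._factors, key, hit)
        return hit

    def whiten(self, arr: np.ndarray, lam: float, phi: float):
        """Solve L z = arr for the cached factor at (lambda, phi); None if V singular."""
        key = (round(float(lam), 12), round(float(phi), 12), id(arr))
        entry = self._lru_get(self._whitened, key)
        # the source array is kept in the entry so its id cannot be recycled
        if entry is None or entry[0] is not arr:
            L, logdet = self.factor(lam, phi)
            if L is None:
                return None, None
            entry = (arr, solve_triangular(L, arr, lower=True, check_finite=False), logdet)
            self._lru_put(self._whitened, key, entry)
        return entry[1], entry[2]


def gls_fit_fixed(X, y, V, k_extra: int = 0, terms=None, params: VarianceParams | None = None) -> GLSFit:
    """Fit GLS with a fixed variance matrix V by maximum likelihood.

    ``k_extra`` counts variance parameters charged to the model over and above
    the regression coefficients and sigma^2, so AICc is comparable across
    models that estimated different numbers of dependence parameters.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n or V.shape != (n, n):
        raise ValueError("X, y and V are not conformable")
    L, logdet = _chol_logdet(V)
    if L is None:
        raise np.linalg.LinAlgError("V is singular; consider PSD repair of its components")
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, rss, sigma2, loglik, xtx_inv = _whitened_ml(Xw, yw, logdet)
    degenerate = xtx_inv is None
    se = np.full(p, np.nan) if degenerate else np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    k = p + 1 + k_extra
    return GLSFit(
        beta=beta,
        se=se,
        sigma2=sigma2,
        loglik=loglik,
        n=n,
        k=k,
        aicc=_aicc(loglik, k, n),
        params=params,
        terms=list(terms) if terms is not None else [],
        degenerate=degenerate,
    )


_MODES = {"both": ("lam", "phi"), "lambda_only": ("lam",), "phi_only": ("phi",), "neither": ()}


def _nll_from_rss(rss: float, n: int, logdet: float, yscale: float) -> float:
    if not np.isfinite(rss) or rss < _DEGENERATE_RSS * max(yscale, 1.0):
        return np.inf
    return 0.5 * (n * np.log(2.0 * np.pi * rss / n) + logdet + n)


def _profile_nll(cache: VarianceCache, X, y, lam, phi, cols=None) -> float:
    """Negative profile log-likelihood at (lambda, phi) via normal equations.

    Fast path for the optimizer: beta and sigma^2 are profiled out with a small
    Cholesky solve on X' V^-1 X rather than a QR factorization. Singular V or a
    singular normal matrix yields +inf.
    """
    Xw, logdet = cache.whiten(X, lam, phi)
    if Xw is None:
        return np.inf
    if cols is not None:
        Xw = Xw[:, cols]
    yw, _ = cache.whiten(y, lam, phi)
    G = Xw.T @ Xw
    b = Xw.T @ yw
    yy = float(yw @ yw)
    try:
        cf = np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        return np.inf
    z = solve_triangular(cf, b, lower=True, check_finite=False)
    rss = yy - float(z @ z)
    return _nll_from_rss(rss, yw.size, logdet, yy)


def _grid_candidates(n_free: int) -> np.ndarray:
    grid1 = np.linspace(0.0, 1.0, GRID_POINTS)
    if n_free == 1:
        return grid1[:, None]
    gl, gp = np.meshgrid(grid1, grid1, indexing="ij")
    return np.column_stack([gl.ravel(), gp.ravel()])


def sweep_profile_grid(cache: VarianceCache, X, y, cols_list, mode: str):
    """Seed-grid negative log-likelihoods for many column-subset models at once.

    Whitens the full design once per grid point and scores every model from the
    shared normal matrix, so an all-subsets enumeration pays the O(n^3) factor
    cost 121 times instead of 121 times per model. Returns ``(candidates,
    vals)`` with ``vals[m, g]`` the negative log-likelihood of model ``m`` at
    grid point ``g`` (aligned with :func:`fit_pgls_spatial`'s seed grid).
    """
    free = _MODES[mode]
    if not free:
        return None, None
    candidates = _grid_candidates(len(free))
    n_models = len(cols_list)
    vals = np.full((n_models, len(candidates)), np.inf)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    for g, theta in enumerate(candidates):
        d = dict(zip(free, theta))
        lam, phi = d.get("lam", 0.0), d.get("phi", 0.0)
        Xw, logdet = cache.whiten(X, lam, phi)
        if Xw is None:
            continue
        yw, _ = cache.whiten(y, lam, phi)
        G = Xw.T @ Xw
        b = Xw.T @ yw
        yy = float(yw @ yw)
        for m, cols in enumerate(cols_list):
            Gs = G[np.ix_(cols, cols)]
            bs = b[cols]
            try:
                cf = np.linalg.cholesky(Gs)
            except np.linalg.LinAlgError:
                continue
            z = solve_triangular(cf, bs, lower=True, check_finite=False)
            vals[m, g] = _nll_from_rss(yy - float(z @ z), n, logdet, yy)
    return candidates, vals


def fit_pgls_spatial(X, y, cov: CovarianceSet, mode: str = "both",
                     cache: VarianceCache | None = None, terms=None, cols=None,
                     seed_nll=None) -> GLSFit:
    """Fit PGLS-spatial, maximizing the profile likelihood over free (lambda, phi).

    ``mode`` chooses which dependence parameters are estimated; excluded ones
    are fixed at zero. Optimization: 11-point-per-dimension grid seed, then
    L-BFGS-B refinement from the 3 best grid points; estimates within 1e-6 of a
    bound are reported exactly at 0 or 1.

    ``cols`` restricts the model to the given columns of ``X`` while whitening
    the full matrix, so a shared ``cache`` amortizes work across the candidate
    models of an all-subsets enumeration.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {sorted(_MODES)}, got {mode!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if cache is None or cache.cov is not cov:
        cache = VarianceCache(cov)
    free = _MODES[mode]

    def unpack(theta):
        d = dict(zip(free, theta))
        return d.get("lam", 0.0), d.get("phi", 0.0)

    def nll(theta):
        theta = np.clip(theta, 0.0, 1.0)
        return _profile_nll(cache, X, y, *unpack(theta), cols=cols)

    if not free:
        best_theta = np.array([])
    else:
        candidates = _grid_candidates(len(free))
        vals = np.asarray(seed_nll) if seed_nll is not None else np.array([nll(c) for c in candidates])
        if vals.shape != (len(candidates),):
            raise ValueError("seed_nll must align with the seed grid")
        if not np.isfinite(vals).any():
            # a perfect fit degenerates the likelihood everywhere: report the
            # flagged fit at the independence point rather than failing
            params0 = VarianceParams(lam=0.0, phi=0.0)
            fit0 = gls_fit_fixed(X if cols is None else X[:, cols], y,
                                 combined_variance(cov, params0),
                                 k_extra=len(free), terms=terms, params=params0)
            if fit0.degenerate:
                return fit0
            raise RuntimeError("profile likelihood not finite anywhere on the seed grid")
        order = np.argsort(vals)
        starts = candidates[order[:N_STARTS]]
        best_theta, best_val = None, np.inf
        for s in starts:
            res = optimize.minimize(
                nll, s, method="L-BFGS-B", bounds=[(0.0, 1.0)] * len(free),
                options={"ftol": OBJ_TOL, "gtol": 1e-10},
            )
            if res.fun < best_val:
                best_val, best_theta = res.fun, np.clip(res.x, 0.0, 1.0)
        if best_theta is None or not np.isfinite(best_val):
            raise RuntimeError("PGLS-spatial optimizer failed to converge from all starts")
        snapped = np.where(best_theta < BOUNDARY_SNAP, 0.0, best_theta)
        snapped = np.where(snapped > 1.0 - BOUNDARY_SNAP, 1.0, snapped)
        if nll(snapped) <= best_val + OBJ_TOL:
            best_theta = snapped

    lam, phi = unpack(best_theta)
    params = VarianceParams(lam=float(lam), phi=float(phi))
    V = combined_variance(cov, params)
    Xm = X if cols is None else X[:, cols]
    return gls_fit_fixed(Xm, y, V, k_extra=len(free), terms=terms, params=params)


def dependence_tests(X, y, cov: CovarianceSet, cache: VarianceCache | None = None) -> DependenceTests:
    """Likelihood-ratio tests for lambda and phi via nested model comparisons.

    Fits the variance model with both, only lambda, only phi, and neither
    parameter free; p(lambda) compares {both} against {phi only} and p(phi)
    compares {both} against {lambda only}, each on 1 df. Because the null pins
    the parameter to the boundary of [0, 1], the plain chi-square reference is
    conservative.
    """
    if cache is None:
        cache = VarianceCache(cov)
    fits = {m: fit_pgls_spatial(X, y, cov, mode=m, cache=cache) for m in _MODES}
    lr_lambda = max(0.0, 2.0 * (fits["both"].loglik - fits["phi_only"].loglik))
    lr_phi = max(0.0, 2.0 * (fits["both"].loglik - fits["lambda_only"].loglik))
    return DependenceTests(
        p_lambda=float(stats.chi2.sf(lr_lambda, df=1)),
        p_phi=float(stats.chi2.sf(lr_phi, df=1)),
        fits=fits,
    )


def pagel_lambda_signal(y, sigma: np.ndarray, h: np.ndarray) -> SignalResult:
    """Estimate Pagel's lambda for one trait by ML on an intercept-only GLS.

    lambda scales the off-diagonal elements of the Brownian-motion covariance:
    1 means trait covariance proportional to relatedness, 0 means phylogenetic
    independence. Significance is a 1-df likelihood-ratio test against
    lambda = 0.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 taxa")
    if np.ptp(y) == 0:
        raise ValueError("constant trait: phylogenetic signal undefined")
    X = np.ones((n, 1))

    def nll(lam: float) -> float:
        V = lambda_transform(sigma, float(np.clip(lam, 0.0, 1.0)))
        L, logdet = _chol_logdet(V)
        if L is None:
            return np.inf
        Xw = solve_triangular(L, X, lower=True)
        yw = solve_triangular(L, y, lower=True)
        _, _, _, loglik, _ = _whitened_ml(Xw, yw, logdet)
        return -loglik

    grid = np.linspace(0.0, 1.0, 21)
    vals = np.array([nll(g) for g in grid])
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if lo == hi:
        lam_hat, ll_hat = grid[best], -vals[best]
    else:
        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-8})
        lam_hat, ll_hat = float(res.x), -float(res.fun)
        if vals[best] < res.fun:
            lam_hat, ll_hat = float(grid[best]), -float(vals[best])
    if lam_hat < BOUNDARY_SNAP:
        lam_hat = 0.0
    elif lam_hat > 1.0 - BOUNDARY_SNAP:
        lam_hat = 1.0
    ll_hat = -nll(lam_hat)
    lr = max(0.0, 2.0 * (ll_hat - (-vals[0])))
    return SignalResult(
        lam_hat=lam_hat,
        loglik_hat=ll_hat,
        p_value=float(stats.chi2.sf(lr, df=1)),
        n=n,
    )


def gls_r_squared(fit: GLSFit, X, y, cov: CovarianceSet) -> float:
    """GLS-metric R^2 = 1 - SSreg / SStot.

    SSreg is the V-weighted residual sum of squares of the fitted model at its
    own dependence optimum; SStot comes from an intercept-only model re-fit
    with its own (lambda, phi) optimum. Not comparable with OLS R^2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if fit.params is None:
        raise ValueError("fit must carry its variance parameters")
    V = combined_variance(cov, fit.params)
    L, _ = _chol_logdet(V)
    resid = solve_triangular(L, y - X @ fit.beta, lower=True)
    ss_reg = float(resid @ resid)
    mode = "both"
    null_fit = fit_pgls_spatial(np.ones((y.size, 1)), y, cov, mode=mode)
    V0 = combined_variance(cov, null_fit.params)
    L0, _ = _chol_logdet(V0)
    resid0 = solve_triangular(L0, y - null_fit.beta[0], lower=True)
    ss_tot = float(resid0 @ resid0)
    if ss_tot <= 0:
        raise ValueError("constant response: total sum of squares is zero")
    return 1.0 - ss_reg / ss_tot
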