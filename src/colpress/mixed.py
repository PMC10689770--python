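"""Random-intercept mixed models fitted by maximum likelihood.

Two fitters live here, both written for the single-random-intercept case
used throughout the package:

* :func:`fit_lmm_ml` — Gaussian linear mixed model
  ``y = X beta + u_group + eps``, ``u ~ N(0, tau2)``, ``eps ~ N(0, sigma2)``,
  fitted by profiling the exact ML likelihood over the variance ratio
  ``lambda = tau2 / sigma2``.  For a fixed ratio the GLS estimate of ``beta``
  and the ML estimate of ``sigma2`` are closed-form (the marginal covariance
  is block diagonal with blocks ``I + lambda * J``, inverted analytically),
  so the whole fit is a one-dimensional optimization.

* :func:`fit_logistic_mixed` — binomial GLMM with logit link,
  ``logit P(y=1) = X beta + u_group``, fitted by adaptive Gauss–Hermite
  quadrature: the integral over each group's random intercept is centered
  and scaled at the conditional mode (found by a vectorized Newton step per
  group) before applying the Gauss–Hermite rule.

ML rather than REML likelihoods are returned so that information criteria
are comparable across fixed-effect structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = ["LMMFit", "GLMMFit", "fit_lmm_ml", "fit_logistic_mixed", "aicc"]


class FitError(RuntimeError):
    """Raised when a model cannot be fitted (singular design, separation...)."""


@dataclass
class LMMFit:
    """A fitted Gaussian random-intercept model (ML)."""

    names: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float
    loglik: float
    n: int
    k: int  # fixed effects (incl. intercept) + sigma2 + tau2
    fitted: np.ndarray = field(repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def marginal_r2(self) -> float:
        """Fixed-effects variance fraction var(X beta) / (var(X beta) + tau2 + sigma2)."""
        vf = float(np.var(self.fitted, ddof=1)) if self.n > 1 else 0.0
        denom = vf + self.tau2 + self.sigma2
        return vf / denom if denom > 0 else 0.0


@dataclass
class GLMMFit:
    """A fitted logit-link random-intercept model (adaptive Gauss-Hermite)."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    tau2: float
    loglik: float
    n: int
    k: int

    def z(self) -> np.ndarray:
        return self.beta / self.se

    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z()))


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion corrected for small samples.

    ``-2 logLik + 2k + 2k(k+1)/(n-k-1)``; requires ``n > k + 1``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = np.unique(np.asarray(groups), return_inverse=True)
    return uniques.astype(np.intp), len(codes)


def _profile_lmm(lam: float, y, X, idx, n_groups):
    """Closed-form GLS step at a fixed variance ratio lambda = tau2/sigma2.

    Returns (neg profiled loglik, beta, sigma2, XtVinvX).
    Uses the Sherman-Morrison inverse of each block I + lam*J.
    """
    n, p = X.shape
    counts = np.bincount(idx, minlength=n_groups).astype(float)
    shrink = lam / (1.0 + lam * counts)  # per group

    def vinv(M):
        # V0^{-1} M with V0 = I + lam * J per block
        gs = np.zeros((n_groups,) + M.shape[1:])
        np.add.at(gs, idx, M)
        return M - (shrink[idx][:, None] if M.ndim == 2 else shrink[idx]) * gs[idx]

    Wy = vinv(y)
    WX = vinv(X)
    XtWX = X.T @ WX
    XtWy = X.T @ Wy
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise FitError("singular design matrix") from exc
    r = y - X @ beta
    quad = float(r @ vinv(r))
    sigma2 = quad / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    logdet = float(np.sum(np.log1p(lam * counts)))
    ll = -0.5 * n * (np.log(2.0 * np.pi) + 1.0 + np.log(sigma2)) - 0.5 * logdet
    return -ll, beta, sigma2, XtWX


def fit_lmm_ml(y, X, groups, names: list[str] | None = None) -> LMMFit:
    """Fit a Gaussian random-intercept LMM by profiled maximum likelihood.

    Parameters
    ----------
    y : (n,) response vector.
    X : (n, p) fixed-effects design, including an intercept column.
    groups : (n,) group labels for the random intercept.
    names : optional fixed-effect names, defaults to ``x0..x{p-1}``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise FitError("singular design matrix (rank deficient)")
    idx, n_groups = _group_codes(groups)
    if n_groups < 2:
        raise FitError("need at least 2 groups for a random intercept")
    if n <= p + 2:
        raise FitError(f"too few observations (n={n}) for k={p + 2} parameters")

    # Profile over s = log1p(lambda); include the lambda = 0 boundary explicitly.
    def obj(s: float) -> float:
        return _profile_lmm(np.expm1(s), y, X, idx, n_groups)[0]

    res = optimize.minimize_scalar(obj, bounds=(0.0, np.log1p(1e6)), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:  # pragma: no cover
        raise FitError(f"profiled-likelihood optimization failed: {res.message}")
    cand = [np.expm1(res.x), 0.0]
    nll, lam = min((_profile_lmm(l, y, X, idx, n_groups)[0], l) for l in cand)
    _, beta, sigma2, XtWX = _profile_lmm(lam, y, X, idx, n_groups)
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    return LMMFit(
        names=list(names),
        beta=beta,
        cov_beta=cov_beta,
        sigma2=sigma2,
        tau2=lam * sigma2,
        loglik=-nll,
        n=n,
        k=p + 2,
        fitted=X @ beta,
    )


# ---------------------------------------------------------------------------
# Logistic GLMM by adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _plain_logistic(y, X, max_iter=100, tol=1e-10):
    """Newton-Raphson (IRLS) logistic regression; returns (beta, cov)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        if np.all(w < 1e-12):
            raise FitError("degenerate logistic weights")
        H = X.T @ (X * w[:, None])
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), g)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular logistic information matrix") from exc
        beta = beta + step
        if np.linalg.norm(beta) > 1e4:
            raise FitError("logistic fit diverged (possible complete separation)")
        if np.max(np.abs(step)) < tol:
            break
    cov = np.linalg.inv(X.T @ (X * (special.expit(X @ beta)
                                    * (1 - special.expit(X @ beta)))[:, None]))
    return beta, cov


def _agq_loglik(beta, log_tau, y, X, idx, n_groups, gh_x, gh_w):
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature."""
    tau = np.exp(log_tau)
    tau2 = tau * tau
    eta0 = X @ beta
    # Conditional mode per group: maximize sum_i logBern + logN(u; 0, tau2).
    u = np.zeros(n_groups)
    for _ in range(50):
        mu = special.expit(eta0 + u[idx])
        score = np.bincount(idx, weights=(y - mu), minlength=n_groups) - u / tau2
        info = np.bincount(idx, weights=mu * (1 - mu), minlength=n_groups) + 1.0 / tau2
        step = score / info
        u += step
        if np.max(np.abs(step)) < 1e-9:
            break
    mu = special.expit(eta0 + u[idx])
    curv = np.bincount(idx, weights=mu * (1 - mu), minlength=n_groups) + 1.0 / tau2
    sd = 1.0 / np.sqrt(curv)

    # h(u) = sum_i [y*log mu + (1-y)*log(1-mu)] - u^2/(2 tau2) - log(tau sqrt(2pi))
    K = gh_x.size
    contrib = np.empty((n_groups, K))
    for k in range(K):
        uk = u + np.sqrt(2.0) * sd * gh_x[k]
        etak = eta0 + uk[idx]
        # Bernoulli loglik via logaddexp for stability
        ll_obs = y * etak - np.logaddexp(0.0, etak)
        h = (np.bincount(idx, weights=ll_obs, minlength=n_groups)
             - 0.5 * uk * uk / tau2 - 0.5 * np.log(2.0 * np.pi * tau2))
        contrib[:, k] = np.log(gh_w[k]) + gh_x[k] ** 2 + h
    per_group = special.logsumexp(contrib, axis=1) + 0.5 * np.log(2.0) + np.log(sd)
    return float(np.sum(per_group))


def fit_logistic_mixed(y, X, groups, names: list[str] | None = None,
                       n_quad: int = 15, fix_tau2: float | None = None) -> GLMMFit:
    """Fit a logit-link random-intercept GLMM by adaptive Gauss-Hermite quadrature.

    Parameters
    ----------
    y : (n,) binary outcome (0/1).
    X : (n, p) design, intercept included.
    groups : (n,) grouping labels (taxonomic family in this package).
    n_quad : number of quadrature nodes (default 15).
    fix_tau2 : if given, the random-intercept variance is held at this value;
        ``fix_tau2=0`` reduces to plain logistic regression.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    classes = np.unique(y)
    if classes.size < 2:
        raise FitError("outcome has a single class; logistic model is undefined")
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("y must be binary 0/1")
    idx, n_groups = _group_codes(groups)

    beta0, cov0 = _plain_logistic(y, X)

    if fix_tau2 is not None and fix_tau2 <= 0.0:
        eta = X @ beta0
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return GLMMFit(names=list(names), beta=beta0, se=np.sqrt(np.diag(cov0)),
                       tau2=0.0, loglik=ll, n=n, k=p)

    gh_x, gh_w = special.roots_hermite(n_quad)

    if fix_tau2 is not None:
        log_tau_fixed = 0.5 * np.log(fix_tau2)

        def nll(th):
            return -_agq_loglik(th, log_tau_fixed, y, X, idx, n_groups, gh_x, gh_w)

        th0 = beta0.copy()
    else:
        def nll(th):
            return -_agq_loglik(th[:p], th[p], y, X, idx, n_groups, gh_x, gh_w)

        th0 = np.concatenate([beta0, [np.log(0.5)]])

    res = optimize.minimize(nll, th0, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 500})
    th = res.x
    if not np.isfinite(res.fun):
        raise FitError("GLMM likelihood not finite at optimum")
    beta = th[:p]
    tau2 = float(fix_tau2) if fix_tau2 is not None else float(np.exp(2.0 * th[p]))
    n_par = th.size

    # Standard errors from a central-difference Hessian of the negative loglik.
    hess = _numeric_hessian(nll, th)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_all = np.full(n_par, np.nan)
    k = p + (1 if fix_tau2 is None else 0)
    return GLMMFit(names=list(names), beta=beta, se=se_all[:p], tau2=tau2,
                   loglik=-float(res.fun), n=n, k=k)


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    m = x.size
    H = np.empty((m, m))
    f0 = f(x)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = eps
            ej = np.zeros(m); ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * eps * eps)
    return H
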