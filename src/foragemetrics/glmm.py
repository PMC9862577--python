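"""Poisson mixed models with per-individual random intercepts and slopes.

The evaluation design regresses prey-encounter counts on standardized
movement metrics with a log link, letting both the intercept and every
metric slope vary among individuals with a full covariance ``T``. The
marginal likelihood is maximized with a Laplace approximation: for each
candidate (beta, T) the per-individual modes of the random effects are
found by Newton iterations (the joint log-density is strictly concave),
and the Gaussian curvature correction is added per individual.

Variance partitioning follows the count-data decomposition used in
behavioral ecology: the total latent variance is split into fixed-slope
variance, random-intercept variance, random-slope variance, and the
distribution-specific variance ln(1 + 1/lambda-bar) of the log-Poisson
(lognormal approximation), giving the R2 shares of each component.
Cross-terms between intercepts and slopes vanish because predictors are
mean-centered.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special

from .types import GlmmFit

_ETA_CAP = 30.0


def standardize(df: pd.DataFrame, cols: list[str],
                stats: pd.DataFrame | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-center and unit-scale columns; returns (frame, stats).

    Pass previously computed ``stats`` to apply a training-fold
    standardization to held-out data.
    """
    out = df.copy()
    if stats is None:
        stats = pd.DataFrame({
            "mean": [df[c].mean() for c in cols],
            "sd": [df[c].std(ddof=0) for c in cols]}, index=cols)
    for c in cols:
        sd = stats.loc[c, "sd"]
        out[c] = (df[c] - stats.loc[c, "mean"]) / (sd if sd > 0 else 1.0)
    return out, stats


def _chol_unpack(theta: np.ndarray, q: int, structure: str) -> np.ndarray:
    L = np.zeros((q, q))
    if structure == "diag":
        L[np.diag_indices(q)] = np.exp(theta)
    else:
        k = 0
        for i in range(q):
            for j in range(i + 1):
                L[i, j] = np.exp(theta[k]) if i == j else theta[k]
                k += 1
    return L


def _n_cov_params(q: int, structure: str) -> int:
    return q if structure == "diag" else q * (q + 1) // 2


def _group_arrays(df: pd.DataFrame, predictors: list[str], response: str,
                  group: str):
    """Sorted design: X (with intercept), y, integer group codes, labels."""
    codes, uniq = pd.factorize(df[group], sort=False)
    order = np.argsort(codes, kind="stable")
    X = np.column_stack([np.ones(len(df))] +
                        [df[c].to_numpy(dtype=float) for c in predictors])
    y = df[response].to_numpy(dtype=float)
    return X[order], y[order], codes[order], list(uniq)


class _LaplaceNll:
    """Negative Laplace marginal log-likelihood, batched over individuals.

    All per-individual reductions (score, information, joint density) are
    bincount/einsum operations over the stacked data, and the G small
    q x q Newton systems are solved in one batched call, so an
    evaluation costs a handful of full-length array passes regardless of
    the number of individuals.
    """

    def __init__(self, X, y, codes, p, q, structure):
        self.X, self.y, self.codes = X, y, codes
        self.p, self.q, self.structure = p, q, structure
        self.G = int(codes.max()) + 1
        self.b = np.zeros((self.G, q))
        self.const = float(special.gammaln(y + 1.0).sum())
        # precompute products for the information matrix
        iu = np.triu_indices(q)
        self._iu = iu
        self._XX = X[:, iu[0]] * X[:, iu[1]]  # n x q(q+1)/2

    def _f_groups(self, eta, Tinv):
        mu = np.exp(eta)
        f = np.bincount(self.codes, self.y * eta - mu, minlength=self.G)
        f -= 0.5 * np.einsum("gi,ij,gj->g", self.b, Tinv, self.b)
        return f, mu

    def __call__(self, theta: np.ndarray) -> float:
        X, y, codes = self.X, self.y, self.codes
        p, q, G = self.p, self.q, self.G
        beta = theta[:p]
        L = _chol_unpack(theta[p:], q, self.structure)
        try:
            Tinv = np.linalg.inv(L @ L.T + 1e-10 * np.eye(q))
        except np.linalg.LinAlgError:
            return 1e12
        logdetT = 2.0 * np.sum(np.log(np.abs(np.diag(L)) + 1e-300))
        off = X @ beta

        def eta_of(b):
            return np.clip(off + np.einsum("ij,ij->i", X, b[codes]),
                           -_ETA_CAP, _ETA_CAP)

        eta = eta_of(self.b)
        f, mu = self._f_groups(eta, Tinv)
        H = None
        for _ in range(50):
            resid = y - mu
            grad = np.column_stack(
                [np.bincount(codes, resid * X[:, k], minlength=G)
                 for k in range(q)]) - self.b @ Tinv
            Hflat = np.column_stack(
                [np.bincount(codes, mu * self._XX[:, m], minlength=G)
                 for m in range(self._XX.shape[1])])
            H = np.zeros((G, q, q))
            H[:, self._iu[0], self._iu[1]] = Hflat
            H[:, self._iu[1], self._iu[0]] = Hflat
            H += Tinv
            try:
                step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                return 1e12
            if not np.all(np.isfinite(step)):
                return 1e12
            t = np.ones(G)
            b_prev, f_prev = self.b, f
            for _ in range(30):
                self.b = b_prev + t[:, None] * step
                eta = eta_of(self.b)
                f, mu = self._f_groups(eta, Tinv)
                bad = f < f_prev - 1e-12
                if not bad.any():
                    break
                t[bad] *= 0.5
            # converged when the damped step no longer moves the modes
            if np.max(np.abs(t[:, None] * step)) < \
                    1e-10 * (1.0 + np.max(np.abs(self.b))):
                break
        Hflat = np.column_stack(
            [np.bincount(codes, mu * self._XX[:, m], minlength=G)
             for m in range(self._XX.shape[1])])
        H = np.zeros((G, q, q))
        H[:, self._iu[0], self._iu[1]] = Hflat
        H[:, self._iu[1], self._iu[0]] = Hflat
        H += Tinv
        sign, logdetH = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            return 1e12
        ll = f.sum() - 0.5 * logdetH.sum() - 0.5 * G * logdetT - self.const
        return -ll


def fit_poisson_glmm(df: pd.DataFrame, predictors: list[str],
                     response: str = "npee", group: str = "individual_id",
                     re_structure: str = "full",
                     compute_se: bool = True) -> GlmmFit:
    """Maximum marginal likelihood fit (Laplace approximation).

    Random effects: intercept plus one slope per predictor, correlated
    (``re_structure="full"``) or independent (``"diag"``). A fit whose
    full covariance collapses to singular is automatically refit with a
    diagonal covariance and flagged. Predictors are expected to be
    standardized on the fitting set.
    """
    if df[group].nunique() < 2:
        raise ValueError("need at least two individuals")
    X, y, codes, labels = _group_arrays(df, predictors, response, group)
    p = q = 1 + len(predictors)

    # starting values: pooled Poisson regression, modest T
    beta0 = _poisson_glm(X, y)
    n_cov = _n_cov_params(q, re_structure)
    theta0 = np.concatenate([beta0, np.full(n_cov, 0.0)])
    if re_structure == "full":
        k = 0
        init = np.zeros(n_cov)
        for i in range(q):
            for j in range(i + 1):
                init[k] = 0.5 * np.log(0.1) if i == j else 0.0
                k += 1
        theta0[p:] = init
    else:
        theta0[p:] = 0.5 * np.log(0.1)

    nll = _LaplaceNll(X, y, codes, p, q, re_structure)
    bounds = [(None, None)] * p
    if re_structure == "diag":
        bounds += [(-7.0, 3.0)] * n_cov
    else:
        k = 0
        for i in range(q):
            for j in range(i + 1):
                bounds.append((-7.0, 3.0) if i == j else (-10.0, 10.0))
                k += 1
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 1000, "ftol": 1e-13,
                                     "gtol": 1e-8, "eps": 1e-7})
    theta = res.x
    Lc = _chol_unpack(theta[p:], q, re_structure)
    T = Lc @ Lc.T
    fallback = False
    if re_structure == "full" and not res.success:
        inner = fit_poisson_glmm(df, predictors, response, group,
                                 re_structure="diag", compute_se=compute_se)
        inner.singular_fallback = True
        return inner

    beta_se = np.full(p, np.nan)
    if compute_se:
        beta_se = _beta_se(nll, theta, p)
    nll(theta)  # leave the modes at the optimum
    ranef = {lab: nll.b[i].copy() for i, lab in enumerate(labels)}
    return GlmmFit(predictors=list(predictors), beta=theta[:p],
                   beta_se=beta_se, T=T, loglik=-float(res.fun),
                   converged=bool(res.success), re_structure=re_structure,
                   singular_fallback=fallback, ranef=ranef,
                   n_obs=len(df), n_groups=len(labels))


def _poisson_glm(X: np.ndarray, y: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """Pooled Poisson regression by IRLS (starting values)."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -_ETA_CAP, _ETA_CAP)
        mu = np.exp(eta)
        W = mu
        try:
            delta = np.linalg.solve((X * W[:, None]).T @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.max(np.abs(delta)) < 1e-10:
            break
    return beta


def _beta_se(nll, theta: np.ndarray, p: int) -> np.ndarray:
    """Standard errors of the fixed effects from the numerical Hessian
    of the negative marginal log-likelihood."""
    n = theta.size
    h = 1e-4 * (1.0 + np.abs(theta))
    H = np.zeros((n, n))
    f0 = nll(theta)
    fp = np.zeros(n)
    fm = np.zeros(n)
    for i in range(n):
        e = np.zeros(n); e[i] = h[i]
        fp[i] = nll(theta + e)
        fm[i] = nll(theta - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i):
            e_i = np.zeros(n); e_i[i] = h[i]
            e_j = np.zeros(n); e_j[j] = h[j]
            fpp = nll(theta + e_i + e_j)
            fmm = nll(theta - e_i - e_j)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j]
                                 + fmm) / (2 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se


def partition_variance(fit: GlmmFit, df: pd.DataFrame,
                       response: str = "npee",
                       lambda_bar: str | float = "observed") -> dict:
    """R2 shares of fixed slopes, random intercepts, and random slopes.

    sigma2_f  = variance of the fixed linear predictor (slopes only);
    sigma2_i  = intercept entry of T;
    sigma2_s  = trace(T_slopes @ cov(X));
    sigma2_d  = ln(1 + 1/lambda_bar), the Poisson-specific variance on
    the latent scale, with lambda_bar the observed mean response by
    default (or a number, or ``"model"`` for exp(beta0 + total/2)).
    """
    Xs = df[fit.predictors].to_numpy(dtype=float)
    eta_fix = Xs @ fit.beta[1:]
    s2_f = float(np.var(eta_fix))
    s2_i = float(fit.T[0, 0])
    if len(fit.predictors) > 0:
        Sx = np.cov(Xs, rowvar=False, ddof=0).reshape(len(fit.predictors), -1)
        s2_s = float(np.trace(fit.T[1:, 1:] @ Sx))
    else:
        s2_s = 0.0
    if lambda_bar == "observed":
        lam = float(df[response].mean())
    elif lambda_bar == "model":
        lam = float(np.exp(fit.beta[0] + 0.5 * (s2_f + s2_i + s2_s)))
    else:
        lam = float(lambda_bar)
    if lam <= 0:
        raise ValueError("mean response must be positive")
    s2_d = float(np.log1p(1.0 / lam))
    total = s2_f + s2_i + s2_s + s2_d
    return {"r2_f": s2_f / total, "r2_i": s2_i / total, "r2_s": s2_s / total,
            "sigma2_f": s2_f, "sigma2_i": s2_i, "sigma2_s": s2_s,
            "sigma2_d": s2_d, "lambda_bar": lam}
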