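"""Random-intercept linear mixed models by REML, with Satterthwaite tests.

The cohort design nests at most two eyes within each participant, so the
only random effect is a person-level intercept:

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, s2_b),  e_ij ~ N(0, s2_e).

With V_i = s2_e I + s2_b J the REML criterion profiles to a function of
the single variance ratio rho = s2_b / s2_e; for a fixed rho the GLS
solution is an OLS fit of group-mean-shrunken variables (the classic
within-group transform y_ij - lambda_i ybar_i with
lambda_i = 1 - (1 + n_i rho)^(-1/2)).  The profiled criterion is
minimised over log rho by Brent search, which makes the fitter fast
enough for Monte-Carlo calibration studies (hundreds of fits at
n ~ 10,000 eyes).

Per-coefficient degrees of freedom use the Satterthwaite approximation:
with C(theta) = (X' V(theta)^-1 X)^-1 and theta = (s2_b, s2_e),

    df_j = 2 C_jj^2 / (g_j' A g_j),

where g_j is the gradient of C_jj in theta (finite differences) and A is
the asymptotic covariance of the REML variance estimates, taken as twice
the inverse Hessian of the -2 restricted log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar


@dataclass
class MixedFitResult:
    """Coefficient table plus variance components of one REML fit."""

    params: pd.DataFrame  # estimate, se, df, ci_low, ci_high, p per term
    sigma_between: float  # person-intercept SD
    sigma_resid: float
    n_obs: int
    n_groups: int
    reml_loglik: float
    converged: bool
    singular: bool  # random-intercept variance estimated at zero

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


class _RandomInterceptREML:
    def __init__(self, X, y, groups):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        groups = np.asarray(groups)
        order = np.argsort(groups, kind="stable")
        self.X = np.ascontiguousarray(X[order])
        self.y = np.ascontiguousarray(y[order])
        g = groups[order]
        change = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
        self.starts = change
        self.counts = np.diff(np.r_[change, len(g)])
        self.expand = np.repeat(np.arange(len(self.counts)), self.counts)
        self.n, self.p = self.X.shape
        self.n_groups = len(self.counts)

    def _gls_pieces(self, rho: float):
        """Transformed normal equations for a given variance ratio."""
        lam = 1.0 - 1.0 / np.sqrt(1.0 + self.counts * rho)
        gx = np.add.reduceat(self.X, self.starts, axis=0) / self.counts[:, None]
        gy = np.add.reduceat(self.y, self.starts) / self.counts
        Xt = self.X - (lam[:, None] * gx)[self.expand]
        yt = self.y - (lam * gy)[self.expand]
        XtX = Xt.T @ Xt
        Xty = Xt.T @ yt
        beta = np.linalg.solve(XtX, Xty)
        r = yt - Xt @ beta
        rss = float(r @ r)
        sign, logdet_XtX = np.linalg.slogdet(XtX)
        if sign <= 0:
            raise np.linalg.LinAlgError("design is rank deficient")
        logdet_W = float(np.sum(np.log1p(self.counts * rho)))
        return beta, rss, XtX, logdet_XtX, logdet_W

    def profiled_crit(self, rho: float) -> float:
        _, rss, _, logdet_XtX, logdet_W = self._gls_pieces(rho)
        return logdet_W + logdet_XtX + (self.n - self.p) * np.log(rss)

    def neg2_reml(self, s2b: float, s2e: float) -> float:
        rho = s2b / s2e
        _, rss, _, logdet_XtX, logdet_W = self._gls_pieces(rho)
        np_ = self.n - self.p
        return (np_ * np.log(2 * np.pi * s2e) + logdet_W + logdet_XtX + rss / s2e)

    def cov_beta(self, s2b: float, s2e: float) -> np.ndarray:
        rho = s2b / s2e
        _, _, XtX, _, _ = self._gls_pieces(rho)
        return s2e * np.linalg.inv(XtX)

    def fit(self):
        res = minimize_scalar(lambda t: self.profiled_crit(np.exp(t)),
                              bounds=(-20.0, 8.0), method="bounded",
                              options={"xatol": 1e-8})
        rho = float(np.exp(res.x))
        singular = False
        if self.profiled_crit(0.0) <= res.fun + 1e-10 or rho < 1e-10:
            rho = 0.0
            singular = True
        beta, rss, XtX, _, _ = self._gls_pieces(rho)
        s2e = rss / (self.n - self.p)
        s2b = rho * s2e
        return beta, s2b, s2e, XtX, bool(res.success), singular


def _satterthwaite_dfs(model: _RandomInterceptREML, s2b: float, s2e: float,
                       singular: bool) -> np.ndarray:
    n, p = model.n, model.p
    fallback = np.full(p, float(n - p))
    if singular or s2b <= 0:
        return fallback
    h_b = max(1e-4 * s2b, 1e-10)
    h_e = 1e-4 * s2e

    def f(tb, te):
        return model.neg2_reml(tb, te)

    try:
        f0 = f(s2b, s2e)
        H = np.empty((2, 2))
        H[0, 0] = (f(s2b + h_b, s2e) - 2 * f0 + f(s2b - h_b, s2e)) / h_b**2
        H[1, 1] = (f(s2b, s2e + h_e) - 2 * f0 + f(s2b, s2e - h_e)) / h_e**2
        H[0, 1] = H[1, 0] = (
            f(s2b + h_b, s2e + h_e) - f(s2b + h_b, s2e - h_e)
            - f(s2b - h_b, s2e + h_e) + f(s2b - h_b, s2e - h_e)
        ) / (4 * h_b * h_e)
        A = 2.0 * np.linalg.inv(H)

        gb = (np.diag(model.cov_beta(s2b + h_b, s2e))
              - np.diag(model.cov_beta(s2b - h_b, s2e))) / (2 * h_b)
        ge = (np.diag(model.cov_beta(s2b, s2e + h_e))
              - np.diag(model.cov_beta(s2b, s2e - h_e))) / (2 * h_e)
        C = np.diag(model.cov_beta(s2b, s2e))
        dfs = np.empty(p)
        for j in range(p):
            g = np.array([gb[j], ge[j]])
            denom = float(g @ A @ g)
            dfs[j] = 2 * C[j] ** 2 / denom if denom > 0 else n - p
        return np.clip(dfs, 1.0, n - p)
    except np.linalg.LinAlgError:
        return fallback


def fit_random_intercept(X, y, groups, term_names=None,
                         alpha: float = 0.05) -> MixedFitResult:
    """REML fit of y on X with a random intercept per group.

    X may be a DataFrame (column names become term names) and must
    already contain an intercept column if one is wanted.
    """
    if isinstance(X, pd.DataFrame):
        term_names = term_names or list(X.columns)
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    if term_names is None:
        term_names = [f"x{j}" for j in range(X.shape[1])]
    if X.ndim != 2 or len(term_names) != X.shape[1]:
        raise ValueError("term names must match the design columns")
    if len(X) != len(y) or len(y) != len(groups):
        raise ValueError("X, y and groups must align")

    model = _RandomInterceptREML(X, y, groups)
    beta, s2b, s2e, XtX, converged, singular = model.fit()
    cov = s2e * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    dfs = _satterthwaite_dfs(model, s2b, s2e, singular)
    tval = beta / se
    pval = 2 * stats.t.sf(np.abs(tval), dfs)
    tq = stats.t.ppf(1 - alpha / 2, dfs)
    table = pd.DataFrame(
        {"estimate": beta, "se": se, "df": dfs,
         "ci_low": beta - tq * se, "ci_high": beta + tq * se, "p": pval},
        index=pd.Index(term_names, name="term"))
    loglik = -0.5 * model.neg2_reml(s2b, s2e)
    return MixedFitResult(
        params=table, sigma_between=float(np.sqrt(s2b)),
        sigma_resid=float(np.sqrt(s2e)), n_obs=model.n,
        n_groups=model.n_groups, reml_loglik=float(loglik),
        converged=converged, singular=singular)
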