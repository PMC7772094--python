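"""Random-intercept linear mixed model: REML fit with Satterthwaite df.

The longitudinal screens need, per region, a model

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, s2_b),  e_ij ~ N(0, s2_e)

with repeated visits j nested in subjects i, plus fractional denominator
degrees of freedom for Wald tests of single coefficients.  The REML
criterion is profiled down to a one-dimensional search over the variance
ratio gamma = s2_b / s2_e (everything else is closed form given gamma),
which makes the thousands of fits in calibration simulations cheap, and the
Satterthwaite approximation

    df = 2 f(theta)^2 / (grad f' Cov(theta) grad f),  f = l' Cov(beta) l

is evaluated with finite differences of the (unprofiled) REML log-likelihood
over theta = (s2_b, s2_e).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_LOG_GAMMA_RANGE = (-18.0, 14.0)


def _group_stats(X: np.ndarray, y: np.ndarray, codes: np.ndarray, n_groups: int):
    p = X.shape[1]
    S = np.zeros((n_groups, p))
    np.add.at(S, codes, X)
    sy = np.zeros(n_groups)
    np.add.at(sy, codes, y)
    n_g = np.bincount(codes, minlength=n_groups).astype(float)
    return S, sy, n_g


class _Suff:
    """Sufficient statistics for the profiled REML criterion."""

    def __init__(self, X, y, codes, n_groups):
        self.X, self.y = X, y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.S, self.sy, self.n_g = _group_stats(X, y, codes, n_groups)
        self.n, self.p = X.shape

    def gls(self, gamma: float):
        """GLS solve at variance ratio gamma; returns beta, A, Q, logdets."""
        c = gamma / (1.0 + self.n_g * gamma)
        A = self.XtX - (self.S * c[:, None]).T @ self.S
        rhs = self.Xty - self.S.T @ (c * self.sy)
        beta = np.linalg.solve(A, rhs)
        Q = self.yty - float(c @ (self.sy ** 2)) - float(beta @ rhs)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1 X not positive definite")
        logdetV = float(np.sum(np.log1p(self.n_g * gamma)))
        return beta, A, max(Q, 1e-300), logdetA, logdetV

    def reml(self, s2_b: float, s2_e: float) -> float:
        """REML log-likelihood at explicit variance components."""
        gamma = s2_b / s2_e
        _, _, Q, logdetA, logdetV = self.gls(gamma)
        n, p = self.n, self.p
        # log|V| + log|X'V^-1 X| = (n - p) log s2_e + log|V*| + log|A|.
        return -0.5 * ((n - p) * np.log(2 * np.pi * s2_e) + logdetV
                       + logdetA + Q / s2_e)

    def profiled_reml(self, gamma: float) -> tuple[float, float]:
        _, _, Q, logdetA, logdetV = self.gls(gamma)
        n, p = self.n, self.p
        s2_e = Q / (n - p)
        ll = -0.5 * ((n - p) * (np.log(2 * np.pi * s2_e) + 1.0) + logdetV
                     + logdetA)
        return ll, s2_e


@dataclass
class RandomInterceptFit:
    """Fitted model: fixed effects, their covariance, variance components."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_subject: float
    sigma2_resid: float
    loglik_reml: float
    n_obs: int
    n_groups: int
    exog_names: list[str]
    _suff: _Suff

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def contrast_variance(self, l: np.ndarray) -> float:
        return float(l @ self.cov_beta @ l)

    def satterthwaite_df(self, l: np.ndarray) -> float:
        """Denominator df for the Wald test of contrast l'beta."""
        l = np.asarray(l, dtype=float)
        theta = np.array([self.sigma2_subject, self.sigma2_resid])
        if theta[0] <= 1e-10 * theta[1]:
            # Boundary fit: no between-subject variance, OLS-like residual df.
            return float(self.n_obs - len(self.beta))

        def f(th):
            gamma = th[0] / th[1]
            _, A, _, _, _ = self._suff.gls(gamma)
            cov = th[1] * np.linalg.inv(A)
            return float(l @ cov @ l)

        h = 1e-4 * theta
        grad = np.empty(2)
        for k in range(2):
            dp = np.zeros(2); dp[k] = h[k]
            grad[k] = (f(theta + dp) - f(theta - dp)) / (2 * h[k])
        H = np.empty((2, 2))
        ll = self._suff.reml
        for a in range(2):
            for b in range(a, 2):
                da = np.zeros(2); da[a] = h[a]
                db = np.zeros(2); db[b] = h[b]
                H[a, b] = H[b, a] = (
                    ll(*(theta + da + db)) - ll(*(theta + da - db))
                    - ll(*(theta - da + db)) + ll(*(theta - da - db))
                ) / (4 * h[a] * h[b])
        try:
            cov_theta = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return float(self.n_obs - len(self.beta))
        denom = float(grad @ cov_theta @ grad)
        if denom <= 0:
            return float(self.n_obs - len(self.beta))
        df = 2.0 * f(theta) ** 2 / denom
        return float(np.clip(df, 1.0, self.n_obs - len(self.beta)))

    def wald_test(self, index: int) -> tuple[float, float, float, float, float]:
        """(estimate, se, df, t, p) for a single coefficient."""
        l = np.zeros(len(self.beta)); l[index] = 1.0
        est = float(self.beta[index])
        se = float(np.sqrt(self.contrast_variance(l)))
        df = self.satterthwaite_df(l)
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), df)
        return est, se, df, t, p


def fit_random_intercept(y, X, groups, exog_names=None) -> RandomInterceptFit:
    """REML fit of a subject-random-intercept model.

    ``groups`` is any array of subject identifiers; ``X`` must include an
    intercept column if one is wanted.  Raises on rank-deficient designs and
    on optimizer failure rather than returning a silent fallback.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != len(X):
        raise ValueError("X must be 2-D and conformable with y")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = codes.max() + 1
    suff = _Suff(X, y, codes, n_groups)

    def neg_profiled(u):
        return -suff.profiled_reml(np.exp(u))[0]

    sol = optimize.minimize_scalar(neg_profiled, bounds=_LOG_GAMMA_RANGE,
                                   method="bounded",
                                   options={"xatol": 1e-10})
    if not sol.success:
        raise RuntimeError(f"REML optimization failed: {sol}")
    gamma = float(np.exp(sol.x))
    # Accept the boundary (gamma -> 0) if it is at least as good.
    ll0, s2e0 = suff.profiled_reml(np.exp(_LOG_GAMMA_RANGE[0]))
    ll, s2_e = suff.profiled_reml(gamma)
    if ll0 >= ll:
        gamma, ll, s2_e = np.exp(_LOG_GAMMA_RANGE[0]), ll0, s2e0
    beta, A, _, _, _ = suff.gls(gamma)
    cov_beta = s2_e * np.linalg.inv(A)
    names = list(exog_names) if exog_names is not None else \
        [f"x{j}" for j in range(X.shape[1])]
    return RandomInterceptFit(beta=beta, cov_beta=cov_beta,
                              sigma2_subject=gamma * s2_e, sigma2_resid=s2_e,
                              loglik_reml=ll, n_obs=len(y), n_groups=int(n_groups),
                              exog_names=names, _suff=suff)
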