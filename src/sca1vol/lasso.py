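"""Penalized mixed-effects selection of volumetric predictors of SARA change.

Change in SARA score at follow-up visits is modelled with fixed effects for
the change in each candidate region, each region-change-by-elapsed-time
interaction, elapsed time, baseline age and gender, plus a subject random
intercept.  Fixed effects (all but the intercept, by default) carry an L1
penalty on the standardized-predictor scale:

    maximize  loglik_ML(beta, s2_b, s2_e) - lambda * sum |beta_penalized|

solved by coordinate descent with soft-thresholding on whitened data,
alternating with profiled maximum-likelihood updates of the variance
components.  An integer lambda grid (default 1..100) is traversed with warm
starts; each lambda's BIC = -2 loglik + k log(n) is recorded (k = active
fixed effects plus the two variance components) and lambda* minimizes it.
Subject-grouped cross-validation error is reported alongside.

Because change scores of co-atrophying regions — and each region's change
versus its change-by-time interaction — are strongly collinear, the lasso
path alone tends to carry correlated extras alongside the true predictors.
The selection report therefore treats the path as a candidate-generation
device: every distinct active set along the path is re-fit by unpenalized
maximum likelihood, scored by an extended BIC (which augments k log n with
a 2*gamma*k*log p term to account for choosing among p candidate terms),
and the winner is greedily backward-pruned under the same score.  The
simpler alternative of reporting the raw active set at lambda* is retained
as an option.

Inference on the selected support is naive post-selection Wald inference,
matching common reporting practice; a warning about its
anti-conservativeness is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import VOI_PREFIX
from .screen import GENDER_REFERENCE, change_from_baseline, decompose_age


@dataclass
class LassoDesign:
    """Raw (unstandardized) design for the penalized model.

    Column 0 is the intercept; ``penalized`` marks the L1-penalized columns.
    Standardization to unit SD happens inside the solver so that held-out
    folds can be standardized with training-fold constants.
    """

    y: np.ndarray                  # delta SARA, points, follow-up rows only
    X: np.ndarray
    col_names: list[str]
    penalized: np.ndarray          # bool mask over columns
    groups: np.ndarray             # subject ids per row

    @property
    def n_obs(self) -> int:
        return len(self.y)


def build_design(cohort: pd.DataFrame, selected_vois: list[str], *,
                 penalize_covariates: bool = True) -> LassoDesign:
    """Assemble the penalized design from a cohort with a SARA column."""
    if "sara" not in cohort.columns:
        raise ValueError("cohort has no 'sara' column")
    if not selected_vois:
        raise ValueError("selected_vois is empty")
    cols = [(v if v.startswith(VOI_PREFIX) else VOI_PREFIX + v)
            for v in selected_vois]
    data = decompose_age(cohort)
    data = change_from_baseline(data, cols + ["sara"])
    data = data[data["visit"] > 1]          # delta SARA defined at follow-ups

    names = ["const"]
    parts = [np.ones(len(data))]
    pen = [False]
    for c in cols:
        names.append("delta_" + c.removeprefix(VOI_PREFIX))
        parts.append(data["delta_" + c].to_numpy())
        pen.append(True)
    for c in cols:
        names.append("delta_" + c.removeprefix(VOI_PREFIX) + ":time")
        parts.append((data["delta_" + c] * data["time_years"]).to_numpy())
        pen.append(True)
    for nm, vals in (("time_years", data["time_years"].to_numpy()),
                     ("baseline_age", data["baseline_age"].to_numpy()),
                     ("gender_F",
                      (data["gender"] != GENDER_REFERENCE).to_numpy(float))):
        names.append(nm)
        parts.append(vals)
        pen.append(penalize_covariates)
    return LassoDesign(y=data["delta_sara"].to_numpy(),
                       X=np.column_stack(parts), col_names=names,
                       penalized=np.array(pen), groups=data["subject"].to_numpy())


# ---------------------------------------------------------------------------
# solver


def _standardize(X: np.ndarray):
    """Unit-SD scaling of non-intercept columns; returns (Xs, means, sds)."""
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    means[0], sds[0] = 0.0, 1.0          # leave the intercept alone
    sds[sds == 0] = 1.0
    return (X - means) / sds, means, sds


def _ml_profile_gamma(r: np.ndarray, codes: np.ndarray, n_g: np.ndarray):
    """Profiled ML over the variance ratio given residuals r."""
    from scipy import optimize
    rr = float(r @ r)
    sums = np.zeros(len(n_g))
    np.add.at(sums, codes, r)
    n = len(r)

    def nll(u):
        g = np.exp(u)
        q = rr - float((g / (1 + n_g * g)) @ (sums ** 2))
        s2 = max(q / n, 1e-12)
        return 0.5 * (n * (np.log(2 * np.pi * s2) + 1) + np.sum(np.log1p(n_g * g)))

    sol = optimize.minimize_scalar(nll, bounds=(-18, 14), method="bounded",
                                   options={"xatol": 1e-8})
    if nll(-18.0) <= sol.fun:
        u = -18.0
    else:
        u = float(sol.x)
    gamma = np.exp(u)
    q = rr - float((gamma / (1 + n_g * gamma)) @ (sums ** 2))
    s2_e = max(q / n, 1e-12)
    return gamma, s2_e


def _whiten(X, y, codes, n_g, gamma):
    c = (1.0 - 1.0 / np.sqrt(1.0 + n_g * gamma)) / n_g
    Xs = np.zeros((len(n_g), X.shape[1]))
    np.add.at(Xs, codes, X)
    ys = np.zeros(len(n_g))
    np.add.at(ys, codes, y)
    return X - (c[codes, None] * Xs[codes]), y - c[codes] * ys[codes]


def _ml_loglik(beta, X, y, codes, n_g, gamma, s2_e):
    r = y - X @ beta
    sums = np.zeros(len(n_g))
    np.add.at(sums, codes, r)
    q = float(r @ r) - float((gamma / (1 + n_g * gamma)) @ (sums ** 2))
    n = len(y)
    return -0.5 * (n * np.log(2 * np.pi * s2_e) + np.sum(np.log1p(n_g * gamma))
                   + q / s2_e)


@dataclass
class PenalizedFit:
    lam: float
    beta_std: np.ndarray          # standardized-predictor scale
    beta: np.ndarray              # original units (back-transformed)
    sigma2_subject: float
    sigma2_resid: float
    loglik: float                 # ML log-likelihood at the solution
    n_active: int                 # active fixed effects incl. intercept
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True


def fit_penalized_lme(design: LassoDesign, lam: float, *,
                      beta0: np.ndarray | None = None,
                      standardization=None,
                      max_outer: int = 60, max_sweeps: int = 400,
                      tol: float = 1e-8) -> PenalizedFit:
    """Solve the L1-penalized mixed model at one penalty value.

    ``beta0`` (standardized scale) warm-starts the coordinate descent;
    ``standardization`` optionally supplies (means, sds) so cross-validation
    can reuse training-fold constants.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if standardization is None:
        Xs, means, sds = _standardize(design.X)
    else:
        means, sds = standardization
        Xs = (design.X - means) / sds
    y = design.y
    _, codes = np.unique(design.groups, return_inverse=True)
    n_g = np.bincount(codes).astype(float)
    p = Xs.shape[1]
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    pen = design.penalized

    gamma, s2_e = _ml_profile_gamma(y - Xs @ beta, codes, n_g)
    trace: list[float] = []
    converged = False
    for outer in range(max_outer):
        Xw, yw = _whiten(Xs, y, codes, n_g, gamma)
        d = np.einsum("ij,ij->j", Xw, Xw)
        r = yw - Xw @ beta
        thresh = lam * s2_e
        for sweep in range(max_sweeps):
            max_delta = 0.0
            for j in range(p):
                bj = beta[j]
                zj = Xw[:, j] @ r + d[j] * bj
                if pen[j]:
                    bj_new = np.sign(zj) * max(abs(zj) - thresh, 0.0) / d[j]
                else:
                    bj_new = zj / d[j]
                if bj_new != bj:
                    r += Xw[:, j] * (bj - bj_new)
                    beta[j] = bj_new
                    max_delta = max(max_delta, abs(bj_new - bj))
            if max_delta < tol * (1 + np.max(np.abs(beta))):
                break
        gamma_new, s2_new = _ml_profile_gamma(y - Xs @ beta, codes, n_g)
        obj = (_ml_loglik(beta, Xs, y, codes, n_g, gamma_new, s2_new)
               - lam * np.sum(np.abs(beta[pen])))
        trace.append(obj)
        var_change = (abs(gamma_new - gamma) / (1 + gamma)
                      + abs(s2_new - s2_e) / s2_e)
        gamma, s2_e = gamma_new, s2_new
        if outer > 0 and var_change < 1e-8 and max_delta < tol * (1 + np.max(np.abs(beta))):
            converged = True
            break
    if not converged and len(trace) >= 2 and abs(trace[-1] - trace[-2]) < 1e-6:
        converged = True
    if not converged:
        raise RuntimeError(f"penalized fit did not converge at lambda={lam}; "
                           f"objective trace tail {trace[-5:]}")

    beta_orig = beta / sds
    beta_orig[0] = beta[0] - float(np.sum(beta[1:] * means[1:] / sds[1:]))
    loglik = _ml_loglik(beta, Xs, y, codes, n_g, gamma, s2_e)
    active = int(np.sum(beta != 0.0))
    return PenalizedFit(lam=lam, beta_std=beta.copy(), beta=beta_orig,
                        sigma2_subject=gamma * s2_e, sigma2_resid=s2_e,
                        loglik=loglik, n_active=active, objective_trace=trace)


@dataclass
class LassoPath:
    lambdas: np.ndarray
    fits: list[PenalizedFit]
    bic: np.ndarray
    lambda_star: float
    col_names: list[str]
    cv_error: np.ndarray | None = None
    failed: list[float] = field(default_factory=list)

    @property
    def best_fit(self) -> PenalizedFit:
        i = int(np.argmin(np.where(np.isnan(self.bic), np.inf, self.bic)))
        return self.fits[i]


def lambda_path(design: LassoDesign, grid=None) -> LassoPath:
    """Warm-started path over an integer penalty grid with BIC selection.

    BIC = -2 loglik + k log(n_obs), k = active fixed effects + 2 variance
    components; ties in BIC resolve to the smallest lambda.
    """
    grid = np.asarray(sorted(grid if grid is not None else range(1, 101)),
                      dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    n = design.n_obs
    fits: list[PenalizedFit | None] = [None] * len(grid)
    failed: list[float] = []
    beta_warm = None
    # Descend from the strongest penalty so warm starts stay sparse.
    for i in range(len(grid) - 1, -1, -1):
        try:
            fit = fit_penalized_lme(design, grid[i], beta0=beta_warm)
        except (RuntimeError, np.linalg.LinAlgError):
            failed.append(float(grid[i]))
            continue
        fits[i] = fit
        beta_warm = fit.beta_std
    bic = np.array([np.nan if f is None
                    else -2 * f.loglik + (f.n_active + 2) * np.log(n)
                    for f in fits])
    if np.all(np.isnan(bic)):
        raise RuntimeError("every lambda on the grid failed")
    star = int(np.nanargmin(bic))       # first (= smallest lambda) minimum
    return LassoPath(lambdas=grid, fits=[f for f in fits], bic=bic,
                     lambda_star=float(grid[star]), col_names=design.col_names,
                     failed=failed)


def cross_validate(design: LassoDesign, grid=None, n_folds: int = 5,
                   seed: int = 0) -> np.ndarray:
    """Subject-grouped CV: mean squared error of fixed-effect predictions of
    delta SARA on held-out subjects, per lambda."""
    grid = np.asarray(sorted(grid if grid is not None else range(1, 101)),
                      dtype=float)
    subjects = np.unique(design.groups)
    if len(subjects) < n_folds:
        raise ValueError(f"{len(subjects)} subjects < {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(subjects)
    folds = np.array_split(perm, n_folds)
    sq_err = np.zeros(len(grid))
    n_test = 0
    for fold in folds:
        test = np.isin(design.groups, fold)
        tr = LassoDesign(y=design.y[~test], X=design.X[~test],
                         col_names=design.col_names,
                         penalized=design.penalized,
                         groups=design.groups[~test])
        beta_warm = None
        _, means, sds = _standardize(tr.X)
        for i in range(len(grid) - 1, -1, -1):
            fit = fit_penalized_lme(tr, grid[i], beta0=beta_warm,
                                    standardization=(means, sds))
            beta_warm = fit.beta_std
            pred = design.X[test] @ fit.beta
            sq_err[i] += float(np.sum((design.y[test] - pred) ** 2))
        n_test += int(test.sum())
    return sq_err / n_test


def _refit_active(design: LassoDesign, idx: list[int]):
    """Unpenalized ML refit on the columns ``idx``: (beta, cov, gamma, s2, ll)."""
    Xa = design.X[:, idx]
    _, codes = np.unique(design.groups, return_inverse=True)
    n_g = np.bincount(codes).astype(float)
    beta = np.zeros(len(idx))
    gamma = s2 = 1.0
    for _ in range(8):
        gamma, s2 = _ml_profile_gamma(design.y - Xa @ beta, codes, n_g)
        Xw, yw = _whiten(Xa, design.y, codes, n_g, gamma)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    gamma, s2 = _ml_profile_gamma(design.y - Xa @ beta, codes, n_g)
    Xw, _ = _whiten(Xa, design.y, codes, n_g, gamma)
    cov = s2 * np.linalg.inv(Xw.T @ Xw)
    ll = _ml_loglik(beta, Xa, design.y, codes, n_g, gamma, s2)
    return beta, cov, gamma, s2, ll


def select_support(path: LassoPath, design: LassoDesign, *,
                   ebic_gamma: float = 0.5) -> list[int]:
    """Choose the reported support from the path's candidate active sets.

    Every distinct active set along the path is re-fit by unpenalized ML and
    scored by the extended BIC -2 ll + (k+2) log n + 2*gamma*k*log p (k =
    fixed effects incl. intercept, p = number of candidate columns); the
    best-scoring set is then greedily backward-pruned under the same score.
    The intercept is never pruned.
    """
    n, p = design.n_obs, design.X.shape[1]
    scores: dict[frozenset, float] = {}

    def score(sup: frozenset) -> float:
        if sup not in scores:
            idx = sorted(sup)
            ll = _refit_active(design, idx)[-1]
            k = len(idx)
            scores[sup] = (-2 * ll + (k + 2) * np.log(n)
                           + 2 * ebic_gamma * k * np.log(p))
        return scores[sup]

    candidates = {frozenset(np.flatnonzero(f.beta_std != 0.0)) | {0}
                  for f in path.fits if f is not None}
    best = min(candidates, key=score)
    best_score = score(best)
    improved = True
    while improved and len(best) > 1:
        improved = False
        for j in sorted(best - {0}):
            cand = frozenset(best - {j})
            if score(cand) < best_score - 1e-9:
                best, best_score, improved = cand, score(cand), True
                break
    return sorted(best)


def report_selection(path: LassoPath, design: LassoDesign, *,
                     criterion: str = "refit-ebic",
                     ebic_gamma: float = 0.5) -> pd.DataFrame:
    """Selected terms with naive post-selection Wald inference.

    ``criterion="refit-ebic"`` (default) selects the support by refit-scored
    extended BIC with backward pruning (see :func:`select_support`);
    ``criterion="lambda-star"`` reports the raw active set of the penalized
    fit at the BIC-minimizing lambda.  z and p come from the unpenalized
    information of the selected set at the refitted variance components;
    they ignore the selection step and are anti-conservative (warning
    emitted).
    """
    from scipy import stats as sps
    warnings.warn("post-selection Wald inference ignores the selection step "
                  "and is anti-conservative", UserWarning, stacklevel=2)
    if criterion == "refit-ebic":
        active = select_support(path, design, ebic_gamma=ebic_gamma)
    elif criterion == "lambda-star":
        active = sorted(set(np.flatnonzero(path.best_fit.beta_std != 0.0))
                        | {0})
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    beta, cov, *_ = _refit_active(design, active)
    se = np.sqrt(np.diag(cov))
    rows = []
    for k, j in enumerate(active):
        z = beta[k] / se[k]
        rows.append({"term": design.col_names[j], "beta": float(beta[k]),
                     "se": float(se[k]), "z": float(z),
                     "p": float(2 * sps.norm.sf(abs(z))), "selected": True})
    for j in range(design.X.shape[1]):
        if j not in active:
            rows.append({"term": design.col_names[j], "beta": 0.0,
                         "se": np.nan, "z": np.nan, "p": np.nan,
                         "selected": False})
    out = pd.DataFrame(rows)
    out.attrs["lambda_star"] = path.lambda_star
    out.attrs["criterion"] = criterion
    return out
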