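"""Baseline group comparison and longitudinal mixed-effects screens.

Three screens over the (ICV-adjusted) regional volumes:

* cross-sectional baseline comparison — OLS of the z-scored volume on group,
  baseline age and gender, so the group coefficient is a standardized effect
  size in SD units;
* group screen — mixed model for change-from-baseline with fixed effects of
  group, elapsed time, baseline age, gender and the focal group-by-time
  interaction, subject random intercepts;
* within-affected screen — same change response in the affected group only,
  with elapsed time as the focal fixed effect.

Age at testing is decomposed into its between-subject (baseline age) and
within-subject (change in age) variance components so the two enter the
models independently.  Family-wise error is controlled by Bonferroni
multiplication over the region family (default 34 regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import RandomInterceptFit, fit_random_intercept
from .regions import VOI_PREFIX

GROUP_REFERENCE = "unaffected"   # affected coded 1 => negative interaction
GENDER_REFERENCE = "M"           # female coded 1
DEFAULT_FAMILY_SIZE = 34


@dataclass
class ModelSpec:
    """Which longitudinal screen to fit for one region."""

    voi: str
    subset: str = "all"            # "all" (group screen) or "affected-only"
    df_method: str = "satterthwaite"   # or "residual"

    def __post_init__(self) -> None:
        if self.subset not in ("all", "affected-only"):
            raise ValueError(f"unknown subset {self.subset!r}")


@dataclass
class LMEResult:
    """Focal fixed effect of one region's mixed-model screen."""

    voi: str
    term: str
    beta: float
    se: float
    df: float
    t: float
    p: float
    p_bonferroni: float | None = None
    fixed_names: list[str] = field(default_factory=list)
    fixed_beta: np.ndarray | None = None
    fixed_cov: np.ndarray | None = None
    sigma2_subject: float = np.nan
    sigma2_resid: float = np.nan


@dataclass
class BaselineResult:
    voi: str
    std_beta: float
    se: float
    t: float
    df: float
    p: float
    ci95: tuple[float, float]
    p_bonferroni: float | None = None


def _require_baseline(cohort: pd.DataFrame) -> pd.Series:
    base = cohort["visit"].eq(1)
    missing = set(cohort["subject"]) - set(cohort.loc[base, "subject"])
    if missing:
        raise ValueError(f"subjects with no baseline visit: {sorted(missing)[:5]}")
    return base


def decompose_age(cohort: pd.DataFrame) -> pd.DataFrame:
    """Split age at testing into baseline_age (between-subject) and
    delta_age (within-subject); their sum reconstructs age exactly."""
    _require_baseline(cohort)
    out = cohort.copy()
    base_age = (out[out["visit"].eq(1)].set_index("subject")["age"])
    out["baseline_age"] = out["subject"].map(base_age)
    out["delta_age"] = out["age"] - out["baseline_age"]
    return out


def change_from_baseline(cohort: pd.DataFrame, columns) -> pd.DataFrame:
    """Add delta_<col> = value - value at the subject's baseline visit."""
    _require_baseline(cohort)
    out = cohort.copy()
    base = out[out["visit"].eq(1)].set_index("subject")
    for col in columns:
        if col not in out.columns:
            raise ValueError(f"no column {col!r} in cohort")
        out["delta_" + col] = out[col] - out["subject"].map(base[col])
    return out


def bonferroni(p_values, m: int):
    """Family-wise corrected p-values: min(1, m * p), elementwise."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * np.asarray(p_values, dtype=float))


def fit_baseline_model(voi: str, cohort: pd.DataFrame) -> BaselineResult:
    """Cross-sectional group contrast in SD units at the baseline visit."""
    col = VOI_PREFIX + voi if not voi.startswith(VOI_PREFIX) else voi
    data = cohort[cohort["visit"].eq(1)]
    for g in ("affected", "unaffected"):
        if (data["group"] == g).sum() < 2:
            raise ValueError(f"need >= 2 baseline observations in group {g!r}")
    z = (data[col] - data[col].mean()) / data[col].std(ddof=1)
    X = np.column_stack([
        np.ones(len(data)),
        (data["group"] != GROUP_REFERENCE).astype(float),
        data["age"],
        (data["gender"] != GENDER_REFERENCE).astype(float),
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(f"rank-deficient baseline design for {voi}")
    import statsmodels.api as sm
    res = sm.OLS(z.to_numpy(), X).fit()
    est, se = res.params[1], res.bse[1]
    df = res.df_resid
    t = res.tvalues[1]
    p = res.pvalues[1]
    half = stats.t.ppf(0.975, df) * se
    return BaselineResult(voi=voi.removeprefix(VOI_PREFIX), std_beta=float(est),
                          se=float(se), t=float(t), df=float(df), p=float(p),
                          ci95=(float(est - half), float(est + half)))


def _prepare(cohort: pd.DataFrame, voi_col: str) -> pd.DataFrame:
    out = cohort
    if "baseline_age" not in out.columns:
        out = decompose_age(out)
    if "delta_" + voi_col not in out.columns:
        out = change_from_baseline(out, [voi_col])
    return out


def fit_lme(spec: ModelSpec, cohort: pd.DataFrame) -> LMEResult:
    """Mixed-effects screen for one region per ``spec``.

    Baseline rows (change = 0 at elapsed time 0) are included; the subject
    random intercept absorbs the within-subject correlation of the repeated
    changes.  Non-convergence raises; it is never silently ignored.
    """
    col = spec.voi if spec.voi.startswith(VOI_PREFIX) else VOI_PREFIX + spec.voi
    data = _prepare(cohort, col)
    if spec.subset == "affected-only":
        data = data[data["group"] == "affected"]
        names = ["const", "time_years", "baseline_age", "gender_F"]
        X = np.column_stack([
            np.ones(len(data)),
            data["time_years"],
            data["baseline_age"],
            (data["gender"] != GENDER_REFERENCE).astype(float),
        ])
        focal = 1
        term = "time_years"
    else:
        names = ["const", "group_affected", "time_years",
                 "group_affected:time_years", "baseline_age", "gender_F"]
        grp = (data["group"] != GROUP_REFERENCE).astype(float)
        X = np.column_stack([
            np.ones(len(data)),
            grp,
            data["time_years"],
            grp * data["time_years"],
            data["baseline_age"],
            (data["gender"] != GENDER_REFERENCE).astype(float),
        ])
        focal = 3
        term = "group_affected:time_years"

    y = data["delta_" + col].to_numpy()
    if np.ptp(y) == 0:
        raise ValueError(f"change in {spec.voi} is constant; nothing to model")
    fit: RandomInterceptFit = fit_random_intercept(y, X, data["subject"], names)
    l = np.zeros(len(names)); l[focal] = 1.0
    est = float(fit.beta[focal])
    se = float(np.sqrt(fit.contrast_variance(l)))
    if spec.df_method == "satterthwaite":
        df = fit.satterthwaite_df(l)
    elif spec.df_method == "residual":
        df = float(fit.n_obs - len(names))
    else:
        raise ValueError(f"unknown df_method {spec.df_method!r}")
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return LMEResult(voi=spec.voi.removeprefix(VOI_PREFIX), term=term, beta=est,
                     se=se, df=df, t=t, p=float(p), fixed_names=names,
                     fixed_beta=fit.beta.copy(), fixed_cov=fit.cov_beta.copy(),
                     sigma2_subject=fit.sigma2_subject,
                     sigma2_resid=fit.sigma2_resid)


def screen_all(cohort: pd.DataFrame, family: str = "group-by-time", *,
               m: int | None = None, voi_names: list[str] | None = None,
               df_method: str = "satterthwaite"
               ) -> tuple[pd.DataFrame, dict[str, LMEResult]]:
    """Run one longitudinal screen over every region.

    Returns a table with the published column layout (VOI, beta, SE, df, t,
    P, P_bonferroni) plus the per-region results keyed by name; per-region
    failures are flagged in the table and do not halt the rest.
    """
    subset = {"group-by-time": "all", "affected-only": "affected-only"}[family]
    if voi_names is None:
        voi_names = [c.removeprefix(VOI_PREFIX) for c in cohort.columns
                     if c.startswith(VOI_PREFIX) and not c.startswith("delta_")]
    m = m if m is not None else (len(voi_names) or DEFAULT_FAMILY_SIZE)
    results: dict[str, LMEResult] = {}
    rows = []
    for voi in voi_names:
        try:
            res = fit_lme(ModelSpec(voi=voi, subset=subset, df_method=df_method),
                          cohort)
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            rows.append({"voi": voi, "beta": np.nan, "se": np.nan, "df": np.nan,
                         "t": np.nan, "p": np.nan, "p_bonferroni": np.nan,
                         "failed": str(exc)})
            continue
        res.p_bonferroni = float(bonferroni([res.p], m)[0])
        results[voi] = res
        rows.append({"voi": voi, "beta": res.beta, "se": res.se, "df": res.df,
                     "t": res.t, "p": res.p, "p_bonferroni": res.p_bonferroni,
                     "failed": ""})
    return pd.DataFrame(rows), results


def baseline_screen(cohort: pd.DataFrame, *, m: int | None = None,
                    voi_names: list[str] | None = None
                    ) -> tuple[pd.DataFrame, dict[str, BaselineResult]]:
    """Standardized baseline group contrasts for every region."""
    if voi_names is None:
        voi_names = [c.removeprefix(VOI_PREFIX) for c in cohort.columns
                     if c.startswith(VOI_PREFIX)]
    m = m if m is not None else (len(voi_names) or DEFAULT_FAMILY_SIZE)
    results: dict[str, BaselineResult] = {}
    rows = []
    for voi in voi_names:
        res = fit_baseline_model(voi, cohort)
        res.p_bonferroni = float(bonferroni([res.p], m)[0])
        results[voi] = res
        rows.append({"voi": voi, "std_beta": res.std_beta, "se": res.se,
                     "t": res.t, "df": res.df, "p": res.p,
                     "p_bonferroni": res.p_bonferroni,
                     "ci95_lo": res.ci95[0], "ci95_hi": res.ci95[1]})
    return pd.DataFrame(rows), results
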