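"""Earliest time at which a region's within-affected change is detectable.

From the within-affected mixed model of change-from-baseline, the predicted
cumulative change at elapsed time t is

    c(t) = b0 + b_time * t,
    Var[c(t)] = v00 + 2 t v0t + t^2 vtt

using the fixed-effect covariance of the intercept and time coefficients.
The detectability horizon is the smallest t > 0 at which the two-sided
confidence interval of c(t) (default 99%, critical value from the t
distribution with the fit's denominator df) excludes zero.  A slope-only
reading — does the CI of b_time itself exclude zero? — is retained as an
alternative method; it yields "detectable at any t" or "never" rather than
a finite horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screen import LMEResult


@dataclass
class DetectabilityResult:
    voi: str
    t_detect: float | None          # years; None = not detectable in horizon
    confidence: float
    method: str

    @property
    def detectable(self) -> bool:
        return self.t_detect is not None


def _coef_indices(fit: LMEResult) -> tuple[int, int]:
    try:
        i0 = fit.fixed_names.index("const")
        it = fit.fixed_names.index("time_years")
    except ValueError as exc:
        raise ValueError("fit must contain intercept and elapsed-time "
                         "coefficients") from exc
    return i0, it


def _ci_excludes_zero(t: float, b0: float, bt: float, v00: float, v0t: float,
                      vtt: float, crit: float) -> bool:
    c = b0 + bt * t
    var = v00 + 2 * t * v0t + t * t * vtt
    if var < 0:
        raise ValueError("fixed-effect covariance not positive semi-definite")
    return abs(c) > crit * np.sqrt(var)


def time_to_detectable_change(fit: LMEResult, *, confidence: float = 0.99,
                              horizon: float = 5.0, tol: float = 1e-4,
                              method: str = "cumulative-change"
                              ) -> DetectabilityResult:
    """Smallest t in (0, horizon] where the CI of the predicted change
    excludes zero, located by grid scan plus bisection to ``tol`` years."""
    if fit.fixed_cov is None or fit.fixed_beta is None:
        raise ValueError("fit must carry the fixed-effect covariance")
    i0, it = _coef_indices(fit)
    b0, bt = float(fit.fixed_beta[i0]), float(fit.fixed_beta[it])
    v00 = float(fit.fixed_cov[i0, i0])
    vtt = float(fit.fixed_cov[it, it])
    v0t = float(fit.fixed_cov[i0, it])
    crit = float(stats.t.ppf(0.5 + confidence / 2, fit.df))

    if method == "slope-ci":
        detectable = abs(bt) > crit * np.sqrt(vtt)
        return DetectabilityResult(fit.voi, 0.0 if detectable else None,
                                   confidence, method)
    if method != "cumulative-change":
        raise ValueError(f"unknown method {method!r}")

    def excluded(t):
        return _ci_excludes_zero(t, b0, bt, v00, v0t, vtt, crit)

    # Scan for the first grid cell where exclusion turns on, then bisect.
    grid = np.linspace(0.0, horizon, 501)
    hit = None
    for lo, hi in zip(grid, grid[1:]):
        if excluded(hi):
            hit = (lo, hi)
            break
    if hit is None:
        return DetectabilityResult(fit.voi, None, confidence, method)
    lo, hi = hit
    if excluded(lo):          # already detectable at the left edge (t -> 0+)
        return DetectabilityResult(fit.voi, float(max(lo, tol)), confidence,
                                   method)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if excluded(mid):
            hi = mid
        else:
            lo = mid
    return DetectabilityResult(fit.voi, float(0.5 * (lo + hi)), confidence, method)


def detectability_closed_form(b0: float, bt: float, v00: float, v0t: float,
                              vtt: float, crit: float) -> float | None:
    """Positive root of (bt^2 - z^2 vtt) t^2 + 2(b0 bt - z^2 v0t) t
    + (b0^2 - z^2 v00) = 0 — the boundary where |c(t)| = z sd(t).

    Returns the smallest positive boundary crossing into detectability, or
    None when no real positive root exists.
    """
    a = bt * bt - crit * crit * vtt
    b = 2 * (b0 * bt - crit * crit * v0t)
    c = b0 * b0 - crit * crit * v00
    if c > 0:
        return 0.0  # already detectable at t = 0
    roots = np.roots([a, b, c]) if a != 0 else (np.array([-c / b]) if b else np.array([]))
    real = sorted(float(r.real) for r in roots
                  if abs(r.imag) < 1e-12 and r.real > 0)
    return real[0] if real else None


def detectability_table(results: dict[str, LMEResult], *,
                        confidence: float = 0.99, horizon: float = 5.0,
                        group_screen_pass: set[str] | None = None
                        ) -> pd.DataFrame:
    """Per-region horizons sorted ascending (non-detectable last), flagging
    regions that also passed the between-group screen."""
    if not results:
        raise ValueError("no fitted results supplied")
    passed = group_screen_pass or set()
    rows = []
    for voi, fit in results.items():
        det = time_to_detectable_change(fit, confidence=confidence,
                                        horizon=horizon)
        rows.append({"voi": voi, "t_detect_years": det.t_detect,
                     "confidence": confidence, "method": det.method,
                     "group_screen_pass": voi in passed})
    df = pd.DataFrame(rows)
    return df.sort_values("t_detect_years", na_position="last",
                          ignore_index=True)
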