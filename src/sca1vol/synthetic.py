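"""Synthetic longitudinal cohorts with known ground truth.

Generates subject-visit tables with the statistical structure the analysis
stages assume: intracranial volume (ICV) drawn per subject and constant over
visits, regional volumes following a power law of ICV with a multiplicative
subject intercept, group-specific linear (optionally accelerating) atrophy,
and a motor score (SARA, 0-40) whose change is driven by pontine volume
change and by the rate of putamen volume change.

The defaults emulate an early-stage SCA1 cohort: 13 affected / 20 unaffected
subjects, visits near 0 / 1.5 / 3.0 years, affected-group ICV mean 1 472 062.4
(SD 116 358.8) mm^3 and unaffected 1 535 453.8 (SD 135 385.6) mm^3, with
per-region atrophy rates and measurement noise calibrated to the precision of
a cohort-scale mixed-effects screen (see :mod:`sca1vol.regions`).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import REGION_NAMES, VOI_PREFIX, region_table

GROUPS = ("affected", "unaffected")

#: SARA is bounded by construction of the instrument.
SARA_MIN, SARA_MAX = 0.0, 40.0


@dataclass
class SimConfig:
    """Generator configuration; every field is a study condition.

    Region-keyed fields (``voi_alpha`` etc.) are dicts over region names;
    group-keyed fields are dicts over ``("affected", "unaffected")``.
    """

    n_affected: int = 13
    n_unaffected: int = 20
    visit_times: tuple[float, ...] = (0.0, 1.5, 3.0)
    visit_jitter_sd: float = 0.1
    icv_mean_by_group: dict[str, float] = field(
        default_factory=lambda: {"affected": 1_472_062.4, "unaffected": 1_535_453.8})
    icv_sd_by_group: dict[str, float] = field(
        default_factory=lambda: {"affected": 116_358.8, "unaffected": 135_385.6})
    baseline_age_mean: float = 53.0
    baseline_age_sd: float = 9.0
    female_rate_by_group: dict[str, float] = field(
        default_factory=lambda: {"affected": 8 / 13, "unaffected": 8 / 20})
    voi_alpha: dict[str, float] = field(default_factory=dict)
    voi_beta: dict[str, float] = field(default_factory=dict)
    slope_by_group: dict[str, dict[str, float]] = field(default_factory=dict)
    accel_by_region: dict[str, float] = field(default_factory=dict)
    subject_intercept_sd: float = 0.05  # relative to the power-law mean
    residual_sd: dict[str, float] = field(default_factory=dict)  # mm^3 per visit
    dropout_prob_affected: float = 3 / 16
    third_visit_cap_unaffected: int | None = 15
    sara_baseline_mean_by_group: dict[str, float] = field(
        default_factory=lambda: {"affected": 7.0, "unaffected": 0.5})
    sara_baseline_sd: float = 3.0
    sara_pons_coef: float = -0.00272        # SARA points per mm^3 pontine change
    sara_putamen_rate_coef: float = -4e-4   # points per mm^3 * yr (rate-of-change term)
    sara_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        tbl = region_table()
        if not self.voi_alpha:
            self.voi_alpha = tbl["alpha"].to_dict()
        if not self.voi_beta:
            self.voi_beta = tbl["beta"].to_dict()
        if not self.slope_by_group:
            self.slope_by_group = {
                "affected": tbl["slope_affected_mm3_yr"].to_dict(),
                "unaffected": {r: 0.0 for r in tbl.index},
            }
        if not self.accel_by_region:
            self.accel_by_region = {r: 0.0 for r in self.voi_alpha}
        if not self.residual_sd:
            self.residual_sd = tbl["residual_sd_mm3"].to_dict()
        self.validate()

    @property
    def regions(self) -> list[str]:
        return list(self.voi_alpha)

    @classmethod
    def restricted(cls, regions: list[str], **overrides) -> "SimConfig":
        """A config simulating only the named regions (defaults otherwise);
        useful for simulation studies that need a single region."""
        tbl = region_table().loc[list(regions)]
        return cls(
            voi_alpha=tbl["alpha"].to_dict(),
            voi_beta=tbl["beta"].to_dict(),
            slope_by_group={
                "affected": tbl["slope_affected_mm3_yr"].to_dict(),
                "unaffected": {r: 0.0 for r in tbl.index},
            },
            accel_by_region={r: 0.0 for r in tbl.index},
            residual_sd=tbl["residual_sd_mm3"].to_dict(),
            **overrides,
        )

    def validate(self) -> None:
        if self.n_affected < 1 or self.n_unaffected < 1:
            raise ValueError("n_affected and n_unaffected must be >= 1")
        times = tuple(self.visit_times)
        if times[0] != 0.0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("visit_times must be strictly increasing from 0")
        for name in ("visit_jitter_sd", "subject_intercept_sd", "sara_noise_sd",
                     "baseline_age_sd", "sara_baseline_sd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0 (got {v!r})")
        for name in ("voi_alpha", "voi_beta", "accel_by_region", "residual_sd"):
            for region, v in getattr(self, name).items():
                if not math.isfinite(v):
                    raise ValueError(f"{name}[{region!r}] is not finite ({v!r})")
        for g, slopes in self.slope_by_group.items():
            for region, v in slopes.items():
                if not math.isfinite(v):
                    raise ValueError(f"slope_by_group[{g!r}][{region!r}] is not finite")
        for name in ("icv_mean_by_group", "icv_sd_by_group"):
            for g, v in getattr(self, name).items():
                if not math.isfinite(v):
                    raise ValueError(f"{name}[{g!r}] is not finite ({v!r})")
        if not 0 <= self.dropout_prob_affected <= 1:
            raise ValueError("dropout_prob_affected must lie in [0, 1]")


@dataclass
class TrueParams:
    """Realized ground-truth parameters stored alongside a simulation."""

    voi_alpha: dict[str, float]
    voi_beta: dict[str, float]
    slope_by_group: dict[str, dict[str, float]]
    accel_by_region: dict[str, float]
    subject_intercept_sd: float
    residual_sd: dict[str, float]
    sara_pons_coef: float
    sara_putamen_rate_coef: float
    sara_noise_sd: float
    seed: int

    @classmethod
    def from_config(cls, config: SimConfig) -> "TrueParams":
        names = [f.name for f in dataclasses.fields(cls)]
        return cls(**{n: getattr(config, n) for n in names})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TrueParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, TrueParams]:
    """Draw one longitudinal cohort under ``config``.

    Returns a tidy subject-visit table (one row per retained visit) and the
    ground-truth parameters used.  Per subject-visit-region:

        VOI = alpha * ICV**beta * (1 + b_subject) + slope_group * t
              + accel * t**2 + noise

    with ``b_subject ~ N(0, subject_intercept_sd)`` on the relative scale and
    visit-level measurement noise ``N(0, residual_sd)`` in mm^3.  The third
    visit is thinned by affected-group dropout and by capping the number of
    unaffected subjects invited back.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    regions = config.regions
    rows: list[dict] = []
    subj_idx = 0
    n_visits = len(config.visit_times)

    for group, n_subj in (("affected", config.n_affected),
                          ("unaffected", config.n_unaffected)):
        # Draw per-subject quantities in a fixed order for determinism.
        icv = rng.normal(config.icv_mean_by_group[group],
                         config.icv_sd_by_group[group], n_subj)
        age0 = rng.normal(config.baseline_age_mean, config.baseline_age_sd, n_subj)
        female = rng.random(n_subj) < config.female_rate_by_group[group]
        b = rng.normal(0.0, config.subject_intercept_sd, (n_subj, len(regions)))
        jitter = rng.normal(0.0, config.visit_jitter_sd, (n_subj, n_visits))
        noise = {
            r: rng.normal(0.0, config.residual_sd[r], (n_subj, n_visits))
            for r in regions
        }
        if group == "affected":
            keep_third = rng.random(n_subj) >= config.dropout_prob_affected
        else:
            keep_third = np.ones(n_subj, dtype=bool)
            cap = config.third_visit_cap_unaffected
            if cap is not None and n_subj > cap:
                invited = rng.choice(n_subj, size=cap, replace=False)
                keep_third[:] = False
                keep_third[invited] = True

        for i in range(n_subj):
            subj_idx += 1
            sid = f"S{subj_idx:03d}"
            for v, t_nominal in enumerate(config.visit_times):
                if v >= 2 and n_visits >= 3 and not keep_third[i]:
                    continue
                # Baseline anchors elapsed time at exactly zero; follow-up
                # timing varies around the nominal schedule.
                t = 0.0 if v == 0 else max(t_nominal + jitter[i, v], 1e-3)
                row = {
                    "subject": sid,
                    "group": group,
                    "gender": "F" if female[i] else "M",
                    "visit": v + 1,
                    "time_years": t,
                    "age": age0[i] + t,
                    "icv": icv[i],
                }
                slopes = config.slope_by_group[group]
                for j, r in enumerate(regions):
                    mean = config.voi_alpha[r] * icv[i] ** config.voi_beta[r]
                    row[VOI_PREFIX + r] = (
                        mean * (1.0 + b[i, j])
                        + slopes[r] * t
                        + config.accel_by_region[r] * t * t
                        + noise[r][i, v]
                    )
                rows.append(row)

    cohort = pd.DataFrame(rows)
    return cohort, TrueParams.from_config(config)


def simulate_sara(cohort: pd.DataFrame, params: TrueParams,
                  config: SimConfig | None = None) -> pd.DataFrame:
    """Add a SARA column driven by pontine change and putamen change rate.

    Per subject, baseline SARA is drawn once; at each follow-up

        dSARA = c_pons * d(pons) + c_putamen_rate * d(putamen) * dt + noise

    where ``d`` denotes change from the subject's baseline and ``dt`` elapsed
    years, so the putamen term is the change-by-time interaction that a
    rate-of-change effect induces.  Scores are clamped to [0, 40].
    """
    for col in (VOI_PREFIX + "pons", VOI_PREFIX + "putamen"):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing required column {col!r}")
    cfg = config if config is not None else SimConfig(seed=params.seed)
    rng = np.random.default_rng(params.seed + 1)

    out = cohort.copy()
    sara = np.empty(len(out))
    for sid, idx in out.groupby("subject", sort=False).groups.items():
        sub = out.loc[idx].sort_values("time_years")
        grp = sub["group"].iloc[0]
        base = rng.normal(cfg.sara_baseline_mean_by_group[grp], cfg.sara_baseline_sd)
        pons0 = sub[VOI_PREFIX + "pons"].iloc[0]
        put0 = sub[VOI_PREFIX + "putamen"].iloc[0]
        for k, (ri, row) in enumerate(sub.iterrows()):
            if k == 0:
                sara[out.index.get_loc(ri)] = np.clip(base, SARA_MIN, SARA_MAX)
                continue
            dt = row["time_years"]
            d_pons = row[VOI_PREFIX + "pons"] - pons0
            d_put = row[VOI_PREFIX + "putamen"] - put0
            delta = (params.sara_pons_coef * d_pons
                     + params.sara_putamen_rate_coef * d_put * dt
                     + rng.normal(0.0, params.sara_noise_sd))
            sara[out.index.get_loc(ri)] = np.clip(base + delta, SARA_MIN, SARA_MAX)
    out["sara"] = sara
    return out


def default_cohort(seed: int = 0, **overrides) -> tuple[pd.DataFrame, TrueParams]:
    """Convenience: cohort + SARA under the default study conditions."""
    config = SimConfig(seed=seed, **overrides)
    cohort, params = simulate_cohort(config)
    cohort = simulate_sara(cohort, params, config)
    return cohort, params
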