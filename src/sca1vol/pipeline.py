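"""Pipeline orchestrator: adjust -> screens -> detectability -> selection.

Stage outputs are written with provenance (config hash, seed, package
version) into a run log so a rerun under the same configuration and seed is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .detect import detectability_table
from .icv import adjust_all
from .io import (read_cohort, write_adjustment_summary, write_cohort,
                 write_screen_results)
from .lasso import build_design, cross_validate, lambda_path, report_selection
from .screen import DEFAULT_FAMILY_SIZE, baseline_screen, screen_all


@dataclass
class PipelineConfig:
    cohort_path: str = "cohort.csv"
    out_dir: str = "results"
    m: int = DEFAULT_FAMILY_SIZE
    confidence: float = 0.99
    horizon_years: float = 5.0
    lambda_min: int = 1
    lambda_max: int = 100
    cv_folds: int = 5
    seed: int = 0
    baseline_only_adjustment: bool = False
    run_adjust: bool = True
    run_screens: bool = True
    run_detectability: bool = True
    run_lasso: bool = True
    selected_vois: list[str] = field(default_factory=list)
    alpha_family: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute the enabled stages in order; returns artifact paths.

    Regions carried into the selection stage are, by default, those passing
    both the between-group screen and the within-affected screen after
    family-wise correction; ``selected_vois`` overrides that list.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.config_hash(), "seed": config.seed,
                  "version": __version__,
                  "config": dataclasses.asdict(config)}
    artifacts: dict[str, str] = {}

    cohort = read_cohort(config.cohort_path)

    if config.run_adjust:
        cohort, summary = adjust_all(
            cohort, baseline_only=config.baseline_only_adjustment)
        write_cohort(cohort, out / "adjusted_cohort.csv")
        write_adjustment_summary(summary, out / "adjustment_summary.json")
        artifacts["adjusted_cohort"] = str(out / "adjusted_cohort.csv")
        artifacts["adjustment_summary"] = str(out / "adjustment_summary.json")

    group_pass: set[str] = set()
    affected_results = None
    if config.run_screens:
        base_tbl, _ = baseline_screen(cohort, m=config.m)
        base_tbl.to_csv(out / "baseline_screen.tsv", sep="\t", index=False)
        artifacts["baseline_screen"] = str(out / "baseline_screen.tsv")

        grp_tbl, grp_results = screen_all(cohort, "group-by-time", m=config.m)
        grp_tbl.to_csv(out / "group_screen.tsv", sep="\t", index=False)
        write_screen_results(grp_results, out / "group_screen.json")
        artifacts["group_screen"] = str(out / "group_screen.tsv")

        aff_tbl, affected_results = screen_all(cohort, "affected-only",
                                               m=config.m)
        aff_tbl.to_csv(out / "affected_screen.tsv", sep="\t", index=False)
        write_screen_results(affected_results, out / "affected_screen.json")
        artifacts["affected_screen"] = str(out / "affected_screen.tsv")

        group_pass = set(grp_tbl.loc[
            grp_tbl["p_bonferroni"] < config.alpha_family, "voi"])

    if config.run_detectability:
        if affected_results is None:
            raise RuntimeError("detectability stage needs the screens stage")
        det = detectability_table(affected_results,
                                  confidence=config.confidence,
                                  horizon=config.horizon_years,
                                  group_screen_pass=group_pass)
        det.to_csv(out / "detectability.tsv", sep="\t", index=False)
        artifacts["detectability"] = str(out / "detectability.tsv")

    if config.run_lasso:
        vois = list(config.selected_vois)
        if not vois and affected_results is not None:
            aff_pass = {v for v, r in affected_results.items()
                        if r.p_bonferroni is not None
                        and r.p_bonferroni < config.alpha_family}
            vois = sorted(group_pass & aff_pass)
        if not vois:
            raise RuntimeError("no regions selected for the penalized model")
        design = build_design(cohort, vois)
        grid = range(config.lambda_min, config.lambda_max + 1)
        path = lambda_path(design, grid)
        path.cv_error = cross_validate(design, grid, config.cv_folds,
                                       seed=config.seed)
        import pandas as pd
        pd.DataFrame({"lambda": path.lambdas, "bic": path.bic,
                      "active": [f.n_active if f else -1 for f in path.fits],
                      "cv_mse": path.cv_error}).to_csv(
            out / "lambda_path.tsv", sep="\t", index=False)
        report = report_selection(path, design)
        report.to_json(out / "selection_report.json", orient="records",
                       indent=2)
        artifacts["lambda_path"] = str(out / "lambda_path.tsv")
        artifacts["selection_report"] = str(out / "selection_report.json")
        provenance["lambda_star"] = path.lambda_star
        provenance["selected_vois"] = vois

    provenance["artifacts"] = artifacts
    (out / "run_log.json").write_text(json.dumps(provenance, indent=2))
    artifacts["run_log"] = str(out / "run_log.json")
    return artifacts
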