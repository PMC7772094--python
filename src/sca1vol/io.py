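"""Readers and writers for cohort tables, fit summaries and atlas stacks.

Cohort tables are plain CSV/TSV, one row per subject-visit, with columns
``subject, group, gender, visit, time_years, age, icv, voi_*`` and optional
``sara``.  Voxel arrays travel as NIfTI-1 files listed in a JSON manifest;
region dictionaries are two-column TSV (code, name).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasStack
from .icv import AdjustmentSummary
from .regions import VOI_PREFIX
from .screen import LMEResult

MANDATORY_COLUMNS = ("subject", "group", "gender", "visit", "age", "icv")
ICV_WARN_BAND = (0.8e6, 2.2e6)


def read_cohort(path) -> pd.DataFrame:
    """Load and validate a cohort table (CSV, or TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns {missing}")
    dup = df.duplicated(subset=["subject", "visit"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["subject", "visit"]].tolist()
        raise ValueError(f"duplicated subject-visit key {tuple(key)} in {path}")
    if not any(c.startswith(VOI_PREFIX) for c in df.columns):
        raise ValueError(f"cohort file {path} has no '{VOI_PREFIX}*' columns")
    bad = df[(df["icv"] < ICV_WARN_BAND[0]) | (df["icv"] > ICV_WARN_BAND[1])]
    if len(bad):
        warnings.warn(f"{len(bad)} rows with ICV outside the plausible band "
                      f"{ICV_WARN_BAND} mm^3")
    df["subject"] = df["subject"].astype(str)
    df["visit"] = df["visit"].astype(int)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    cohort.to_csv(path, sep=sep, index=False)


def write_adjustment_summary(summary: AdjustmentSummary, path) -> None:
    payload = {
        "fits": {k: dataclasses.asdict(v) for k, v in summary.fits.items()},
        "mu_raw": summary.mu_raw, "sigma_raw": summary.sigma_raw,
        "mu_adj": summary.mu_adj, "sigma_adj": summary.sigma_adj,
        "failed": summary.failed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_screen_results(results: dict[str, LMEResult], path) -> None:
    """Machine-readable screen output including the fixed-effect covariance
    each region's detectability computation needs."""
    payload = {}
    for voi, r in results.items():
        payload[voi] = {
            "term": r.term, "beta": r.beta, "se": r.se, "df": r.df,
            "t": r.t, "p": r.p, "p_bonferroni": r.p_bonferroni,
            "fixed_names": r.fixed_names,
            "fixed_beta": list(map(float, r.fixed_beta)),
            "fixed_cov": [list(map(float, row)) for row in r.fixed_cov],
            "sigma2_subject": r.sigma2_subject, "sigma2_resid": r.sigma2_resid,
        }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_screen_results(path) -> dict[str, LMEResult]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for voi, d in payload.items():
        out[voi] = LMEResult(voi=voi, term=d["term"], beta=d["beta"],
                             se=d["se"], df=d["df"], t=d["t"], p=d["p"],
                             p_bonferroni=d.get("p_bonferroni"),
                             fixed_names=d["fixed_names"],
                             fixed_beta=np.array(d["fixed_beta"]),
                             fixed_cov=np.array(d["fixed_cov"]),
                             sigma2_subject=d.get("sigma2_subject", np.nan),
                             sigma2_resid=d.get("sigma2_resid", np.nan))
    return out


def write_region_dictionary(region_dictionary: dict[int, str], path) -> None:
    lines = [f"{code}\t{name}" for code, name in sorted(region_dictionary.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_region_dictionary(path) -> dict[int, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            code, name = line.split("\t")
            out[int(code)] = name
    return out


def write_atlas_stack(stack: AtlasStack, out_dir) -> Path:
    """Write all arrays as NIfTI plus a JSON manifest; returns manifest path."""
    import nibabel as nib
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(stack.voxel_dims) + [1.0])

    def save(arr, name, dtype):
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine),
                 out_dir / name)
        return name

    manifest = {
        "voxel_dims": list(stack.voxel_dims),
        "target_intensity": save(stack.target_intensity, "target.nii.gz", np.float32),
        "target_jacobian": save(stack.target_jacobian, "target_jac.nii.gz", np.float32),
        "mask": save(stack.mask, "mask.nii.gz", np.uint8),
        "candidates": [],
    }
    for i in range(stack.n_candidates):
        entry = {
            "intensity": save(stack.candidate_intensities[i],
                              f"cand{i:02d}.nii.gz", np.float32),
            "jacobian": save(stack.candidate_jacobians[i],
                             f"cand{i:02d}_jac.nii.gz", np.float32),
            "labels": [save(lm, f"cand{i:02d}_labels{s}.nii.gz", np.int16)
                       for s, lm in enumerate(stack.candidate_labels[i])],
        }
        manifest["candidates"].append(entry)
    write_region_dictionary(stack.region_dictionary, out_dir / "regions.tsv")
    manifest["region_dictionary"] = "regions.tsv"
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_atlas_stack(manifest_path) -> AtlasStack:
    import nibabel as nib
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    m = json.loads(manifest_path.read_text())

    def load(name):
        return np.asarray(nib.load(root / name).dataobj)

    return AtlasStack(
        target_intensity=load(m["target_intensity"]).astype(float),
        target_jacobian=load(m["target_jacobian"]).astype(float),
        candidate_intensities=[load(c["intensity"]).astype(float)
                               for c in m["candidates"]],
        candidate_labels=[[load(n).astype(np.int32) for n in c["labels"]]
                          for c in m["candidates"]],
        candidate_jacobians=[load(c["jacobian"]).astype(float)
                             for c in m["candidates"]],
        mask=load(m["mask"]).astype(bool),
        voxel_dims=tuple(m["voxel_dims"]),
        region_dictionary=read_region_dictionary(root / m["region_dictionary"]),
    )
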