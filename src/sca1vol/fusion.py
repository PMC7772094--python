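"""Multi-atlas labelling core: morphologically matched exemplar selection,
similarity-weighted majority-vote label fusion, and volume extraction.

The procedure mirrors multi-atlas pipelines in which each study image is
normalized to a template, candidates are ranked by Pearson correlation of
their Jacobian-determinant maps with the target's within the brain mask,
the top-k morphological "exemplars" contribute every one of their label
sets, and each labelled image votes per voxel with a weight derived from
local intensity similarity to the target.  Registration itself is out of
scope: all inputs must already share one voxel grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .atlas import AtlasStack


@dataclass
class ExemplarSelection:
    """Per-candidate similarity scores and the chosen top-k identifiers."""

    scores: np.ndarray          # Pearson r per candidate; NaN = undefined
    chosen: list[int]           # candidate indices, best first

    def __post_init__(self) -> None:
        if len(set(self.chosen)) != len(self.chosen):
            raise ValueError("chosen exemplars must be unique")


@dataclass
class LabelMap:
    labels: np.ndarray                  # integer region codes, 0 = background
    region_dictionary: dict[int, str]

    def __post_init__(self) -> None:
        codes = set(np.unique(self.labels)) - {0}
        missing = codes - set(self.region_dictionary)
        if missing:
            raise ValueError(f"label codes missing from region dictionary: "
                             f"{sorted(missing)}")


def jacobian_similarity(target_jac: np.ndarray, candidate_jacs,
                        mask: np.ndarray, *, log_scale: bool = True) -> np.ndarray:
    """Pearson correlation of each candidate's Jacobian map with the target's.

    Computed over in-mask voxels, by default on the log scale (Jacobian
    determinants are ratio-scaled).  A zero-variance vector yields NaN with a
    warning; downstream selection ranks NaN last.
    """
    m = np.asarray(mask, dtype=bool)
    if m.sum() < 2:
        raise ValueError("mask must contain at least 2 voxels")
    tv = np.asarray(target_jac)[m].astype(float)
    if log_scale:
        tv = np.log(tv)
    if not np.all(np.isfinite(tv)):
        raise ValueError("non-finite target Jacobian values inside mask")
    tv = tv - tv.mean()
    t_norm = np.sqrt(tv @ tv)
    scores = np.empty(len(candidate_jacs))
    for i, cand in enumerate(candidate_jacs):
        cv = np.asarray(cand)[m].astype(float)
        if log_scale:
            cv = np.log(cv)
        if not np.all(np.isfinite(cv)):
            raise ValueError(f"non-finite Jacobian values in candidate {i}")
        cv = cv - cv.mean()
        c_norm = np.sqrt(cv @ cv)
        if t_norm == 0 or c_norm == 0:
            warnings.warn(f"zero-variance Jacobian vector for candidate {i}; "
                          "similarity undefined, ranked last")
            scores[i] = np.nan
        else:
            scores[i] = float(tv @ cv / (t_norm * c_norm))
    return scores


def select_exemplars(scores, k: int) -> ExemplarSelection:
    """Top-k candidates by similarity, descending; ties and NaNs handled
    deterministically (ties broken by candidate index order, NaN last)."""
    scores = np.asarray(scores, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(scores):
        warnings.warn(f"requested k={k} exemplars but only {len(scores)} "
                      "candidates; selecting all")
        k = len(scores)
    keys = np.where(np.isnan(scores), -np.inf, scores)
    order = np.argsort(-keys, kind="stable")
    return ExemplarSelection(scores=scores, chosen=[int(i) for i in order[:k]])


def _patch_weight(target: np.ndarray, candidate: np.ndarray,
                  patch_radius: int, eps: float) -> np.ndarray:
    """Voxelwise weight 1 / (eps + local mean squared intensity difference)."""
    sq = (target - candidate) ** 2
    size = 2 * patch_radius + 1
    msd = ndimage.uniform_filter(sq, size=size, mode="nearest")
    return 1.0 / (eps + msd)


def fuse_labels(stack: AtlasStack, selection: ExemplarSelection, *,
                patch_radius: int = 1, eps: float = 1e-6) -> LabelMap:
    """Similarity-weighted majority-vote fusion over the chosen exemplars.

    Every label set of every chosen exemplar casts one vote per voxel,
    weighted by the inverse local (cubic-patch) mean squared intensity
    difference between that exemplar's intensity image and the target.
    Output label = argmax of summed weights; vote ties resolve to the lowest
    label code.  Voxels outside the mask are background (0).
    """
    if not selection.chosen:
        raise ValueError("exemplar selection is empty")
    shape = stack.target_intensity.shape
    codes = sorted({int(c)
                    for ci in selection.chosen
                    for lm in stack.candidate_labels[ci]
                    for c in np.unique(lm)})
    best_votes = np.full(shape, -1.0)
    best_label = np.zeros(shape, dtype=np.int32)
    weights = {ci: _patch_weight(stack.target_intensity,
                                 stack.candidate_intensities[ci],
                                 patch_radius, eps)
               for ci in selection.chosen}
    # Ascending code order + strict improvement = lowest-code tie-break.
    for code in codes:
        votes = np.zeros(shape)
        for ci in selection.chosen:
            w = weights[ci]
            for lm in stack.candidate_labels[ci]:
                votes += w * (lm == code)
        better = votes > best_votes
        best_votes[better] = votes[better]
        best_label[better] = code
    best_label[~stack.mask] = 0
    rdict = dict(stack.region_dictionary)
    for code in codes:
        if code != 0:
            rdict.setdefault(code, f"region_{code}")
    return LabelMap(labels=best_label, region_dictionary=rdict)


def extract_volumes(label_map: LabelMap, voxel_dims) -> dict[str, float]:
    """Per-region volumes in mm^3 plus ``icv`` = total labelled volume."""
    dims = np.asarray(voxel_dims, dtype=float)
    if np.any(dims <= 0):
        raise ValueError("voxel dimensions must be positive")
    vox_mm3 = float(np.prod(dims))
    labels = label_map.labels
    counts = np.bincount(labels.ravel())
    record: dict[str, float] = {}
    for code, name in sorted(label_map.region_dictionary.items()):
        n = counts[code] if code < len(counts) else 0
        record[name] = float(n) * vox_mm3
    record["icv"] = float(labels.size - (counts[0] if len(counts) else 0)) * vox_mm3
    return record
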