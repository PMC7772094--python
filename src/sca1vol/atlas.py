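"""Synthetic voxel-array fixtures for the multi-atlas labelling stage.

Emulates the inputs the label-fusion core consumes after registration:
a target intensity image, warped candidate-atlas intensities and label maps,
per-candidate Jacobian-determinant maps of the deformation to template
space, and a brain mask — all on one grid.  No attempt is made to mimic MR
appearance (no bias fields, no Rician noise); the fixtures control only the
statistical features fusion and exemplar selection depend on: label
disagreement rates and Jacobian-map correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class AtlasStack:
    """Target plus candidate atlases on a common voxel grid."""

    target_intensity: np.ndarray
    target_jacobian: np.ndarray
    candidate_intensities: list[np.ndarray]
    candidate_labels: list[list[np.ndarray]]  # per candidate, per label set
    candidate_jacobians: list[np.ndarray]
    mask: np.ndarray
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    region_dictionary: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.target_intensity.shape
        arrays = ([self.target_jacobian, self.mask]
                  + self.candidate_intensities + self.candidate_jacobians
                  + [lm for sets in self.candidate_labels for lm in sets])
        if any(a.shape != shape for a in arrays):
            raise ValueError("all arrays in an AtlasStack must share one grid shape")
        for jac in [self.target_jacobian] + self.candidate_jacobians:
            if np.any(jac[self.mask] <= 0):
                raise ValueError("Jacobian determinants must be positive inside mask")

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_intensities)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma)


def _standardize(a: np.ndarray, mask: np.ndarray) -> np.ndarray:
    v = a[mask]
    return (a - v.mean()) / v.std()


def simulate_atlas_stack(grid_shape=(32, 32, 32), n_candidates: int = 10,
                         n_label_sets: int = 5, seed: int = 0, *,
                         n_regions: int = 4, disagreement_rate: float = 0.05,
                         jacobian_correlations=None,
                         intensity_perturbation: float = 0.3,
                         voxel_dims=(1.0, 1.0, 1.0)) -> AtlasStack:
    """Generate an :class:`AtlasStack` with controlled structure.

    ``jacobian_correlations`` fixes the *sample* Pearson correlation (inside
    the mask, on the log scale) between each candidate's Jacobian map and the
    target's, by Gram-Schmidt construction; defaults to values equally spaced
    in [0.1, 0.95].  ``disagreement_rate`` is the fraction of in-mask voxels
    at which each candidate label map deviates from the shared ground-truth
    parcellation.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(grid_shape)
    if jacobian_correlations is None:
        jacobian_correlations = np.linspace(0.95, 0.1, n_candidates)
    jacobian_correlations = np.asarray(jacobian_correlations, dtype=float)
    if len(jacobian_correlations) != n_candidates:
        raise ValueError("need one Jacobian correlation per candidate")

    # Ellipsoidal brain mask.
    grids = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape], indexing="ij")
    mask = sum(g ** 2 for g in grids) <= 0.85

    target = _smooth_field(rng, shape, sigma=2.0)

    # Ground-truth parcellation: Voronoi cells of random seed points in-mask.
    centers = np.array([rng.uniform(-0.7, 0.7, len(shape)) for _ in range(n_regions)])
    dists = np.stack([sum((g - c) ** 2 for g, c in zip(grids, ctr))
                      for ctr in centers])
    truth = np.where(mask, np.argmin(dists, axis=0) + 1, 0).astype(np.int16)

    # Target Jacobian: exp of a smooth standardized field.
    t_field = _standardize(_smooth_field(rng, shape, 2.0), mask)
    target_jac = np.exp(0.2 * t_field)

    in_mask = np.flatnonzero(mask.ravel())
    cand_int, cand_jac, cand_labels = [], [], []
    for c in range(n_candidates):
        cand_int.append(target + intensity_perturbation
                        * _smooth_field(rng, shape, 2.0))
        # Residualize a fresh field against the target's inside the mask so
        # the requested sample correlation holds exactly on the log scale.
        raw = _standardize(_smooth_field(rng, shape, 2.0), mask)
        tv, rv = t_field[mask], raw[mask]
        resid = raw.copy()
        resid[mask] = rv - (rv @ tv / (tv @ tv)) * tv
        resid = _standardize(resid, mask)
        r = jacobian_correlations[c]
        mix = r * t_field + np.sqrt(max(0.0, 1 - r * r)) * resid
        cand_jac.append(np.exp(0.2 * mix))

        sets = []
        for _ in range(n_label_sets):
            lm = truth.copy().ravel()
            n_flip = int(round(disagreement_rate * len(in_mask)))
            if n_flip:
                flip = rng.choice(in_mask, size=n_flip, replace=False)
                lm[flip] = rng.integers(1, n_regions + 1, size=n_flip)
            sets.append(lm.reshape(shape))
        cand_labels.append(sets)

    region_dictionary = {i: f"region_{i}" for i in range(1, n_regions + 1)}
    return AtlasStack(target_intensity=target, target_jacobian=target_jac,
                      candidate_intensities=cand_int, candidate_labels=cand_labels,
                      candidate_jacobians=cand_jac, mask=mask,
                      voxel_dims=tuple(voxel_dims),
                      region_dictionary=region_dictionary)
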