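"""Exemplar selection, label fusion and volume extraction contracts."""

import numpy as np
import pytest

from sca1vol.atlas import AtlasStack, simulate_atlas_stack
from sca1vol.fusion import (LabelMap, extract_volumes, fuse_labels,
                            jacobian_similarity, select_exemplars)


def tiny_stack(cand_intensities, cand_labels, target=None, mask=None):
    shape = cand_labels[0][0].shape
    target = np.zeros(shape) if target is None else target
    mask = np.ones(shape, bool) if mask is None else mask
    jac = np.ones(shape)
    return AtlasStack(target_intensity=target, target_jacobian=jac,
                      candidate_intensities=cand_intensities,
                      candidate_labels=cand_labels,
                      candidate_jacobians=[jac.copy() for _ in cand_intensities],
                      mask=mask)


class TestJacobianSimilarity:
    def test_identical_map_scores_one(self):
        t = np.exp(np.random.default_rng(0).normal(0, 0.2, (5, 5, 5)))
        m = np.ones(t.shape, bool)
        assert jacobian_similarity(t, [t.copy()], m)[0] == pytest.approx(1.0)

    def test_affine_negation_scores_minus_one_on_raw_scale(self):
        t = 1.0 + 0.3 * np.random.default_rng(1).random((4, 4, 4))
        m = np.ones(t.shape, bool)
        r = jacobian_similarity(t, [2.0 - t], m, log_scale=False)[0]
        assert r == pytest.approx(-1.0)

    def test_five_voxel_hand_computed_pearson(self):
        # Oracle: the Pearson formula evaluated directly on the 5 pairs.
        x = np.array([1.0, 1.1, 0.9, 1.2, 0.8])
        y = np.array([1.0, 1.2, 0.8, 1.3, 0.7])
        n = 5
        expected = ((n * (x * y).sum() - x.sum() * y.sum())
                    / np.sqrt(n * (x ** 2).sum() - x.sum() ** 2)
                    / np.sqrt(n * (y ** 2).sum() - y.sum() ** 2))
        got = jacobian_similarity(x.reshape(5, 1, 1), [y.reshape(5, 1, 1)],
                                  np.ones((5, 1, 1), bool), log_scale=False)[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_candidate_is_nan_with_warning_and_ranked_last(self):
        t = 1.0 + 0.2 * np.random.default_rng(2).random((4, 4, 4))
        flat = np.full(t.shape, 1.3)
        m = np.ones(t.shape, bool)
        with pytest.warns(UserWarning, match="zero-variance"):
            scores = jacobian_similarity(t, [t, flat], m)
        assert np.isnan(scores[1])
        sel = select_exemplars(scores, 2)
        assert sel.chosen == [0, 1]

    def test_mask_with_single_voxel_rejected(self):
        t = np.ones((3, 3, 3))
        m = np.zeros_like(t, bool)
        m[0, 0, 0] = True
        with pytest.raises(ValueError, match="mask"):
            jacobian_similarity(t, [t], m)


class TestSelectExemplars:
    def test_top_k_by_score(self):
        sel = select_exemplars([0.9, 0.5, 0.1], 2)
        assert sel.chosen == [0, 1]

    def test_ties_broken_by_identifier_order(self):
        sel = select_exemplars([0.4, 0.4, 0.4], 2)
        assert sel.chosen == [0, 1]

    def test_k_larger_than_pool_selects_all_with_warning(self):
        with pytest.warns(UserWarning, match="selecting all"):
            sel = select_exemplars([0.2, 0.8], 5)
        assert sel.chosen == [1, 0]

    def test_ladder_ranking_matches_independently_computed_correlations(
            self, atlas_ladder):
        scores = jacobian_similarity(atlas_ladder.target_jacobian,
                                     atlas_ladder.candidate_jacobians,
                                     atlas_ladder.mask)
        # Oracle: plain Pearson on the generated log arrays.
        m = atlas_ladder.mask
        ref = [np.corrcoef(np.log(atlas_ladder.target_jacobian[m]),
                           np.log(c[m]))[0, 1]
               for c in atlas_ladder.candidate_jacobians]
        np.testing.assert_allclose(scores, ref, atol=1e-12)
        assert select_exemplars(scores, 5).chosen == [0, 1, 2, 3, 4]
        np.testing.assert_allclose(scores, [0.9, 0.7, 0.5, 0.3, 0.1], atol=1e-9)


class TestFuseLabels:
    def test_unanimous_votes_win_regardless_of_weights(self):
        stack = simulate_atlas_stack((12, 12, 12), 4, 3, seed=1,
                                     disagreement_rate=0.0)
        sel = select_exemplars(
            jacobian_similarity(stack.target_jacobian,
                                stack.candidate_jacobians, stack.mask), 4)
        fused = fuse_labels(stack, sel)
        ref = stack.candidate_labels[0][0].copy()
        ref[~stack.mask] = 0
        assert np.array_equal(fused.labels, ref)

    def test_weighted_majority_prefers_intensity_matched_atlas(self):
        shape = (4, 4, 4)
        target = np.zeros(shape)
        # Candidate 0 matches the target exactly (huge weight), candidate 1
        # is far off (small weight); their label maps disagree everywhere.
        a = [np.full(shape, 2, np.int32)]
        b = [np.full(shape, 1, np.int32)]
        stack = tiny_stack([target.copy(), target + 10.0], [a, b], target)
        fused = fuse_labels(stack, select_exemplars([0.9, 0.8], 2))
        assert (fused.labels == 2).all()

    def test_vote_tie_resolves_to_lowest_label_code(self):
        shape = (3, 3, 3)
        target = np.zeros(shape)
        a = [np.full(shape, 5, np.int32)]
        b = [np.full(shape, 2, np.int32)]
        stack = tiny_stack([target.copy(), target.copy()], [a, b], target)
        fused = fuse_labels(stack, select_exemplars([0.5, 0.5], 2))
        assert (fused.labels == 2).all()

    def test_atlas_order_permutation_leaves_output_unchanged(self, atlas_ladder):
        scores = jacobian_similarity(atlas_ladder.target_jacobian,
                                     atlas_ladder.candidate_jacobians,
                                     atlas_ladder.mask)
        sel = select_exemplars(scores, 5)
        fused = fuse_labels(atlas_ladder, sel)
        shuffled = select_exemplars(scores, 5)
        shuffled.chosen = shuffled.chosen[::-1]
        assert np.array_equal(fused.labels,
                              fuse_labels(atlas_ladder, shuffled).labels)

    def test_single_exemplar_single_label_set_is_identity(self):
        stack = simulate_atlas_stack((10, 10, 10), 1, 1, seed=3,
                                     disagreement_rate=0.1)
        fused = fuse_labels(stack, select_exemplars([1.0], 1))
        ref = stack.candidate_labels[0][0].copy()
        ref[~stack.mask] = 0
        assert np.array_equal(fused.labels, ref)

    def test_output_labels_subset_of_input_labels(self, atlas_ladder):
        sel = select_exemplars(
            jacobian_similarity(atlas_ladder.target_jacobian,
                                atlas_ladder.candidate_jacobians,
                                atlas_ladder.mask), 3)
        fused = fuse_labels(atlas_ladder, sel)
        inputs = set()
        for ci in sel.chosen:
            for lm in atlas_ladder.candidate_labels[ci]:
                inputs |= set(np.unique(lm))
        assert set(np.unique(fused.labels)) <= inputs | {0}

    def test_empty_selection_rejected(self, atlas_ladder):
        from sca1vol.fusion import ExemplarSelection
        with pytest.raises(ValueError, match="empty"):
            fuse_labels(atlas_ladder,
                        ExemplarSelection(scores=np.array([]), chosen=[]))


class TestExtractVolumes:
    def test_voxel_count_times_voxel_volume(self):
        labels = np.zeros((5, 5, 5), np.int32)
        labels.ravel()[:10] = 7
        lm = LabelMap(labels, {7: "pons"})
        rec = extract_volumes(lm, (1.0, 1.0, 1.0))
        assert rec["pons"] == 10.0
        assert rec["icv"] == 10.0
        rec2 = extract_volumes(lm, (0.5, 0.5, 2.0))
        assert rec2["pons"] == pytest.approx(5.0)

    def test_empty_label_map_gives_zero_volumes(self):
        lm = LabelMap(np.zeros((4, 4, 4), np.int32), {1: "a", 2: "b"})
        rec = extract_volumes(lm, (1, 1, 1))
        assert rec == {"a": 0.0, "b": 0.0, "icv": 0.0}

    def test_random_map_matches_bruteforce_counting_and_conserves_icv(self, rng):
        labels = rng.integers(0, 6, size=(9, 9, 9)).astype(np.int32)
        lm = LabelMap(labels, {c: f"r{c}" for c in range(1, 6)})
        rec = extract_volumes(lm, (1.1, 0.9, 1.3))
        vox = 1.1 * 0.9 * 1.3
        total = 0.0
        for code in range(1, 6):
            n = sum(1 for v in labels.ravel() if v == code)  # naive oracle
            assert rec[f"r{code}"] == pytest.approx(n * vox)
            total += rec[f"r{code}"]
        assert rec["icv"] == pytest.approx(total)

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            LabelMap(np.full((2, 2, 2), 9, np.int32), {1: "a"})

    def test_nonpositive_voxel_dims_rejected(self):
        lm = LabelMap(np.zeros((2, 2, 2), np.int32), {})
        with pytest.raises(ValueError, match="positive"):
            extract_volumes(lm, (1.0, 0.0, 1.0))
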