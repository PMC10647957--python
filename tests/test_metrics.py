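"""TRE, Dice, Jaccard, Hausdorff, and landmark transformation."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from mireg import (
    AffineParams,
    LandmarkSet,
    SegmentationMask,
    dice,
    evaluate_pair,
    hausdorff,
    jaccard,
    transform_landmarks,
    tre,
)


def _lm(offsets=None, tumor=False):
    base = {
        "up": (2.0, 16.0), "dp": (30.0, 16.0), "lp": (16.0, 2.0),
        "rp": (16.0, 30.0), "midd": (10.0, 16.0), "cntr": (15.5, 15.5),
        "B4": (16.0, 28.0), "B9": (16.0, 4.0), "B0": (4.0, 16.0),
    }
    if tumor:
        base.update(tmr1=(18.0, 20.0), tmr2=(22.0, 20.0), tmr3=(20.0, 22.0),
                    tmr4=(20.0, 18.0), ctmr=(20.0, 20.0))
    if offsets:
        base = {k: (v[0] + offsets[0], v[1] + offsets[1]) for k, v in base.items()}
    return LandmarkSet(base)


class TestLandmarkSet:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            LandmarkSet({"skull_top": (0, 0)})

    def test_missing_required_names_rejected(self):
        with pytest.raises(ValueError):
            LandmarkSet({"up": (0, 0)})

    def test_tumor_flag(self):
        assert not _lm().has_tumor
        assert _lm(tumor=True).has_tumor
        assert len(_lm(tumor=True).names) == 14


class TestTransformLandmarks:
    def test_identity_leaves_points(self):
        lm = _lm()
        out = transform_landmarks(lm, AffineParams.identity(), (32, 32))
        assert out.points == lm.points

    def test_translation_moves_every_point(self):
        out = transform_landmarks(_lm(), AffineParams(1, 0, 0, 1, 3, 4), (32, 32))
        for name, xy in _lm().points.items():
            assert out.points[name] == (xy[0] + 3, xy[1] + 4)

    def test_rotation_about_center_matrix_oracle(self):
        params = AffineParams(0, -1, 1, 0, 0, 0)  # 90 degrees about center
        out = transform_landmarks(_lm(), params, (32, 32))
        assert np.allclose(out.points["cntr"], (15.5, 15.5))
        c = np.array([15.5, 15.5])
        for name, xy in _lm().points.items():
            expected = params.matrix @ (np.array(xy) - c) + c
            assert np.allclose(out.points[name], expected, atol=1e-12)

    def test_spacing_converts_mm_to_pixels_once(self):
        # 2 px shift at 0.5 mm spacing moves points by 1 mm
        out = transform_landmarks(_lm(), AffineParams(1, 0, 0, 1, 2, 0), (32, 32),
                                  spacing=(0.5, 0.5))
        assert out.points["cntr"][0] - _lm().points["cntr"][0] == pytest.approx(1.0)


class TestTRE:
    def test_identical_sets_score_zero(self):
        per, mean = tre(_lm(), _lm())
        assert mean == 0 and all(v == 0 for v in per.values())

    def test_three_four_five_offset(self):
        a, b = _lm(), _lm()
        pts = dict(b.points)
        pts["up"] = (pts["up"][0] + 3, pts["up"][1] + 4)
        per, _ = tre(a, LandmarkSet(pts))
        assert per["up"] == pytest.approx(5.0)

    def test_mean_matches_loop_oracle(self, rng):
        a = _lm(tumor=True)
        jitter = {n: tuple(np.array(xy) + rng.normal(0, 2, 2))
                  for n, xy in a.points.items()}
        b = LandmarkSet(jitter)
        per, mean = tre(a, b)
        expected = np.mean(
            [np.linalg.norm(np.array(a.points[n]) - np.array(b.points[n]))
             for n in a.names]
        )
        assert mean == pytest.approx(expected, abs=1e-12)

    def test_name_mismatch_lists_offenders(self):
        with pytest.raises(ValueError, match="tmr1"):
            tre(_lm(tumor=True), _lm())


class TestOverlapMetrics:
    def test_identical_masks_perfect_scores(self):
        m = np.zeros((8, 8), int)
        m[2:6, 2:6] = 1
        assert dice(m, m) == 1.0 and jaccard(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a, b = np.zeros((8, 8), int), np.zeros((8, 8), int)
        a[:2], b[6:] = 1, 1
        assert dice(a, b) == 0.0 and jaccard(a, b) == 0.0

    def test_half_overlap_dice(self):
        a, b = np.zeros((4, 4), int), np.zeros((4, 4), int)
        a[0, :2] = 1  # |A| = 2
        b[0, 1:3] = 1  # |B| = 2, one shared pixel
        assert dice(a, b) == pytest.approx(0.5)
        assert jaccard(a, b) == pytest.approx(1 / 3)

    def test_jaccard_dice_identity_on_random_masks(self, rng):
        for _ in range(100):
            a = (rng.random((16, 16)) > 0.6).astype(int)
            b = (rng.random((16, 16)) > 0.6).astype(int)
            d, j = dice(a, b), jaccard(a, b)
            assert abs(j - d / (2 - d)) < 1e-12

    @given(inter=st.integers(0, 20), only_a=st.integers(0, 20),
           only_b=st.integers(0, 20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_jaccard_dice_identity_for_all_overlap_counts(
        self, inter, only_a, only_b
    ):
        assume(inter + only_a + only_b > 0)
        a = np.zeros((1, 64), int)
        b = np.zeros((1, 64), int)
        a[0, : inter + only_a] = 1
        b[0, :inter] = 1
        b[0, inter + only_a : inter + only_a + only_b] = 1
        d, j = dice(a, b), jaccard(a, b)
        assert j == pytest.approx(d / (2 - d), abs=1e-12)

    def test_both_empty_score_one_with_warning(self):
        z = np.zeros((4, 4), int)
        with pytest.warns(UserWarning):
            assert dice(z, z) == 1.0
        with pytest.warns(UserWarning):
            assert jaccard(z, z) == 1.0

    def test_symmetry(self, rng):
        a = (rng.random((12, 12)) > 0.5).astype(int)
        b = (rng.random((12, 12)) > 0.5).astype(int)
        assert dice(a, b) == dice(b, a)
        assert jaccard(a, b) == jaccard(b, a)


class TestHausdorff:
    def test_identical_masks_zero(self):
        m = np.zeros((8, 8), int)
        m[2:6, 2:6] = 1
        assert hausdorff(m, m) == 0.0

    def test_single_pixels_give_euclidean_distance(self):
        a, b = np.zeros((8, 8), int), np.zeros((8, 8), int)
        a[0, 0], b[3, 0] = 1, 1
        assert hausdorff(a, b) == pytest.approx(3.0)

    def test_spacing_scales_distance(self):
        a, b = np.zeros((8, 8), int), np.zeros((8, 8), int)
        a[0, 0], b[3, 0] = 1, 1
        assert hausdorff(a, b, spacing=(0.5, 0.5)) == pytest.approx(1.5)

    def test_matches_brute_force_oracle(self, rng):
        """Symmetric Hausdorff equals the O(n^2) max-min over boundary sets."""
        from mireg.metrics import _boundary_points

        for _ in range(10):
            a = np.zeros((20, 20), int)
            b = np.zeros((20, 20), int)
            for m in (a, b):
                pts = rng.integers(2, 18, size=(rng.integers(3, 50), 2))
                m[pts[:, 0], pts[:, 1]] = 1
            pa, pb = _boundary_points(a.astype(bool)), _boundary_points(b.astype(bool))
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
            brute = max(d.min(axis=1).max(), d.min(axis=0).max())
            assert hausdorff(a, b) == pytest.approx(brute, abs=1e-12)

    def test_empty_mask_rejected(self):
        m = np.zeros((4, 4), int)
        m2 = m.copy()
        m2[1, 1] = 1
        with pytest.raises(ValueError):
            hausdorff(m, m2)

    def test_monotone_degradation_under_translation(self):
        """Sliding a convex mask away never raises Dice/Jaccard and never
        lowers Hausdorff."""
        base = np.zeros((40, 40), int)
        rr, cc = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        base[((rr - 20) ** 2 + (cc - 20) ** 2) <= 64] = 1
        prev_d, prev_j, prev_h = 1.0, 1.0, 0.0
        for shift in range(1, 6):
            moved = np.roll(base, shift, axis=1)
            d, j, h = dice(base, moved), jaccard(base, moved), hausdorff(base, moved)
            assert d <= prev_d + 1e-12 and j <= prev_j + 1e-12
            assert h >= prev_h - 1e-12
            prev_d, prev_j, prev_h = d, j, h


class TestEvaluatePair:
    def test_perfect_registration_scores_perfectly(self, aligned_pair):
        fixed, moving, truth = aligned_pair
        rec = evaluate_pair(
            fixed, moving, AffineParams.identity(),
            truth.landmarks_fixed, truth.landmarks_moving,
            mask_fixed=truth.mask_fixed, mask_moving_warped=truth.mask_moving,
        )
        assert rec["tre_post_mm"] == 0.0
        assert rec["dice_post"] == 1.0
        assert rec["jaccard_post"] == 1.0
        assert rec["hausdorff_post_mm"] == 0.0
        assert rec["stratum"] == "tumor"

    def test_identity_registration_post_equals_pre(self, phantom_pair):
        fixed, moving, truth = phantom_pair
        rec = evaluate_pair(fixed, moving, AffineParams.identity(),
                            truth.landmarks_fixed, truth.landmarks_moving)
        assert rec["tre_post_mm"] == pytest.approx(rec["tre_pre_mm"])

    def test_true_params_reduce_tre_to_zero(self, phantom_pair):
        """The generator's ground-truth affine is exactly recoverable."""
        fixed, moving, truth = phantom_pair
        rec = evaluate_pair(fixed, moving, truth.params,
                            truth.landmarks_fixed, truth.landmarks_moving)
        assert rec["tre_post_mm"] < 0.5
        assert rec["tre_pre_mm"] > 1.0
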