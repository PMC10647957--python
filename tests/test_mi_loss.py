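"""Normalization, soft joint histograms, and the MI loss."""

import numpy as np
import pytest

from mireg import (
    MILossConfig,
    NormalizationStats,
    entropy,
    mi_loss,
    mutual_information,
    normalize,
    soft_joint_histogram,
)
from mireg.autodiff import Tensor
from mireg.mi_loss import JointHistogram, soft_histogram


def hard_joint_mi(a, b, n_bins, base=2.0):
    """Independent counting oracle: nearest-bin-center hard 2D histogram MI."""

    def to_units(x):
        lo, hi = x.min(), x.max()
        pad = 1e-6 * max(hi - lo, 1.0)
        return (x - (lo - pad)) / ((hi + pad) - (lo - pad)) * (n_bins - 1)

    ia = np.clip(np.rint(to_units(a.ravel())), 0, n_bins - 1).astype(int)
    ib = np.clip(np.rint(to_units(b.ravel())), 0, n_bins - 1).astype(int)
    joint = np.zeros((n_bins, n_bins))
    for x, y in zip(ia, ib):
        joint[x, y] += 1
    joint /= joint.sum()
    pf, pm = joint.sum(1)[:, None], joint.sum(0)[None, :]
    m = joint > 0
    return joint, float((joint[m] * np.log(joint[m] / (pf * pm)[m])).sum() / np.log(base))


class TestNormalize:
    def test_explicit_stats(self):
        out = normalize(np.array([[0.0, 2.0], [0.0, 2.0]]),
                        NormalizationStats(mean=1.0, std=1.0))
        assert np.array_equal(out, [[-1, 1], [-1, 1]])

    def test_self_stats_give_zero_mean_unit_std(self, rng):
        out = normalize(rng.random((32, 32)))
        assert abs(out.mean()) < 1e-9 and abs(out.std() - 1) < 1e-9

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.ones((4, 4)))

    def test_nonpositive_std_rejected(self):
        with pytest.raises(ValueError):
            NormalizationStats(mean=0.0, std=0.0)


class TestSoftJointHistogram:
    def test_identical_constant_pair_concentrates_in_one_bin(self):
        h = soft_joint_histogram(np.full((4, 4), 3.0), np.full((4, 4), 3.0), 8)
        assert h.probs.max() == pytest.approx(1.0)
        assert h.probs.sum() == pytest.approx(1.0)

    def test_bin_center_intensities_reproduce_hard_counts(self, rng):
        n_bins = 8
        a = rng.integers(0, n_bins, (16, 16)).astype(float)
        b = rng.integers(0, n_bins, (16, 16)).astype(float)
        hard, _ = hard_joint_mi(a, b, n_bins)
        for bw in (1.0, 0.5, 0.01):
            soft = soft_joint_histogram(a, b, n_bins, bw).probs
            assert np.abs(soft - hard).max() < 1e-5

    def test_marginals_equal_soft_1d_histograms(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        h = soft_joint_histogram(a, b, 16, 1.0)
        assert np.allclose(h.marginal_fixed(), soft_histogram(a, 16, 1.0), atol=1e-12)
        assert np.allclose(h.marginal_moving(), soft_histogram(b, 16, 1.0), atol=1e-12)

    def test_table_is_normalized_and_nonnegative(self, rng):
        h = soft_joint_histogram(rng.random((8, 8)), rng.random((8, 8)), 32, 0.7)
        assert h.probs.min() >= 0
        assert h.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shape_mismatch_and_bad_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            soft_joint_histogram(rng.random((4, 4)), rng.random((5, 5)), 8)
        with pytest.raises(ValueError):
            soft_joint_histogram(rng.random((4, 4)), rng.random((4, 4)), 1)


class TestMutualInformation:
    def test_two_matched_symbols_give_one_bit(self):
        h = JointHistogram(np.diag([0.5, 0.5]), np.zeros(2), np.zeros(2), 1.0)
        assert mutual_information(h) == pytest.approx(1.0, abs=1e-9)

    def test_independent_uniform_table_gives_zero(self):
        h = JointHistogram(np.full((2, 2), 0.25), np.zeros(2), np.zeros(2), 1.0)
        assert mutual_information(h) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("k", [2, 4, 8, 64])
    def test_diagonal_table_gives_log2_k_bits(self, k):
        h = JointHistogram(np.diag(np.full(k, 1 / k)), np.zeros(2), np.zeros(2), 1.0)
        assert mutual_information(h) == pytest.approx(np.log2(k), abs=1e-9)

    def test_unnormalized_table_rejected(self):
        with pytest.raises(ValueError):
            JointHistogram(np.diag([0.5, 0.6]), np.zeros(2), np.zeros(2), 1.0)


class TestMILoss:
    def test_self_loss_is_negated_entropy(self, rng):
        img = rng.random((64, 64))
        # bandwidth 0.5 makes the per-pixel assignment one-hot, so the
        # self-joint is exactly diagonal and MI(F,F) = H(F)
        cfg = MILossConfig(n_bins=16, bandwidth=0.5)
        assert mi_loss(img, img, cfg) == pytest.approx(
            -entropy(img, 16, 0.5), abs=1e-9
        )

    def test_independent_images_near_zero(self, rng):
        a, b = rng.random((64, 64)), rng.random((64, 64))
        loss = mi_loss(a, b, MILossConfig(n_bins=8))
        assert abs(loss) < 0.05  # small positive MI bias expected

    def test_monotone_remap_preserves_mi_at_bin_resolution(self, rng):
        # quantized image whose levels sit near (but not on) distinct bin
        # centers after a strictly monotone remap
        levels = np.array([0.0, 1.2, 2.1, 3.3, 3.9, 5.1, 6.2, 7.0])
        idx = rng.integers(0, 8, (64, 64))
        img = idx.astype(float)
        remapped = levels[idx]
        cfg = MILossConfig(n_bins=8, bandwidth=0.5)
        assert abs(mi_loss(img, remapped, cfg) - (-entropy(img, 8, 0.5))) < 0.1

    def test_symmetry(self, rng):
        for _ in range(5):
            a, b = rng.random((32, 32)), rng.random((32, 32))
            h_ab = mutual_information(soft_joint_histogram(a, b, 16))
            h_ba = mutual_information(soft_joint_histogram(b, a, 16))
            assert abs(h_ab - h_ba) < 1e-9

    def test_nonnegativity_and_entropy_upper_bound(self, rng):
        for _ in range(10):
            a, b = rng.random((24, 24)), rng.random((24, 24))
            mi = mutual_information(soft_joint_histogram(a, b, 12, 0.8))
            assert mi >= -1e-9
            assert mi <= min(entropy(a, 12, 0.8), entropy(b, 12, 0.8)) + 1e-6

    def test_soft_mi_converges_to_hard_oracle_as_bandwidth_shrinks(self, rng):
        a = rng.random((32, 32))
        b = 0.5 * a + 0.5 * rng.random((32, 32))
        _, hard = hard_joint_mi(a, b, 8)
        errs = []
        for bw in (1.0, 0.5, 0.1):
            soft = mutual_information(soft_joint_histogram(a, b, 8, bw))
            errs.append(abs(soft - hard))
        assert errs[0] >= errs[1] - 1e-12 and errs[1] >= errs[2] - 1e-12
        assert errs[2] < 1e-6

    def test_gradient_flows_to_warped_intensities(self, rng):
        from scipy import ndimage

        f = ndimage.gaussian_filter(rng.random((16, 16)), 1.0)
        m = ndimage.gaussian_filter(rng.random((16, 16)), 1.0)
        tm = Tensor(m.copy(), requires_grad=True)
        loss = mi_loss(Tensor(f), tm, MILossConfig(n_bins=8))
        loss.backward()
        assert tm.grad is not None and np.isfinite(tm.grad).all()
        # spot-check one coordinate against finite differences
        i, j = 5, 7
        h = 1e-6
        mp, mm = m.copy(), m.copy()
        mp[i, j] += h
        mm[i, j] -= h
        fd = (mi_loss(f, mp, MILossConfig(n_bins=8))
              - mi_loss(f, mm, MILossConfig(n_bins=8))) / (2 * h)
        assert abs(tm.grad[i, j] - fd) < 1e-5

    def test_normalized_variant_bounded_by_one(self, rng):
        img = rng.random((32, 32))
        cfg = MILossConfig(n_bins=8, bandwidth=0.5, normalized=True)
        assert -mi_loss(img, img, cfg) == pytest.approx(1.0, abs=1e-6)


class TestRegistrationSignal:
    def test_translation_sweep_peaks_at_true_offset(self):
        """MI over a 1D translation sweep is maximized at the true shift."""
        from mireg import AffineRanges, PhantomSpec, make_pair, warp_with_affine
        from mireg.spatial_transformer import AffineParams

        spec = PhantomSpec(size=96, tumor=False, seed=21)
        ranges = AffineRanges(0.0, 0.0, (1.0, 1.0), 0.0)
        fixed, moving_aligned, _ = make_pair(spec, ranges, seed=21)
        true_shift = 4.0
        moving = warp_with_affine(
            moving_aligned.pixels, AffineParams(1, 0, 0, 1, -true_shift, 0),
            fill=float(moving_aligned.pixels.min()),
        )
        scores = {}
        for s in np.arange(-8.0, 8.5, 1.0):
            warped = warp_with_affine(moving, AffineParams(1, 0, 0, 1, s, 0),
                                      fill=float(moving.min()))
            _, mi = hard_joint_mi(fixed.pixels, warped, 32)
            scores[s] = mi
        best = max(scores, key=scores.get)
        assert abs(best - true_shift) <= 1.0
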