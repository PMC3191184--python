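import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from punctacoloc import (
    ChannelImage,
    PixelPairs,
    RegionOfInterest,
    coloc_summary,
    icq,
    manders,
    pdm_image,
    pearson,
)
from punctacoloc.exceptions import ConstantChannelError, ZeroSignalError

from .oracles import brute_icq, brute_manders, brute_pearson


def pairs(a, b):
    return PixelPairs.from_arrays(a, b)


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson(pairs([0, 3, 9, 4], [0, 3, 9, 4])) == pytest.approx(1.0)

    def test_inverted_channel_is_minus_one(self):
        a = np.array([0, 3, 9, 4])
        assert pearson(pairs(a, 255 - a)) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # A=(0,1,2,3), B=(1,3,2,4): covariance 4, both deviation norms sqrt(5)
        assert pearson(pairs([0, 1, 2, 3], [1, 3, 2, 4])) == pytest.approx(0.8)

    def test_constant_channel_is_signaled(self):
        with pytest.raises(ConstantChannelError):
            pearson(pairs([1, 1, 1], [0, 2, 4]))


class TestManders:
    def test_strictly_positive_channels_give_unity(self):
        m1, m2 = manders(pairs([3, 9, 1], [4, 2, 8]))
        assert m1 == 1.0 and m2 == 1.0

    def test_disjoint_supports_give_zero(self):
        m1, m2 = manders(pairs([10, 0, 5, 0], [0, 7, 0, 3]))
        assert m1 == 0.0 and m2 == 0.0

    def test_hand_computed_example(self):
        m1, m2 = manders(pairs([10, 0, 5], [0, 7, 3]))
        assert m1 == pytest.approx(5 / 15) and m2 == pytest.approx(3 / 10)

    def test_all_zero_channel_is_signaled(self):
        with pytest.raises(ZeroSignalError):
            manders(pairs([0, 0, 0], [1, 2, 3]))


class TestICQ:
    def test_identical_channels_reach_half(self):
        # no pixel equals the mean, every product is a positive square
        a = np.array([10, 10, 200, 200, 200])
        assert icq(pairs(a, a)) == pytest.approx(0.5)

    def test_inverted_channel_reaches_minus_half(self):
        a = np.array([10, 10, 200, 200, 200])
        assert icq(pairs(a, 255 - a)) == pytest.approx(-0.5)

    def test_hand_counted_example(self):
        # A=(1,2,3,4), B=(4,1,2,8): signed products (-,+,-,+) -> 2/4 - 0.5 = 0
        assert icq(pairs([1, 2, 3, 4], [4, 1, 2, 8])) == pytest.approx(0.0)

    def test_zero_products_count_in_denominator_only(self):
        # pixels at a channel mean contribute product exactly 0: here the
        # signed products are (+, 0, 0), so only 1 of 3 pixels is positive
        # (counting zeros as positive would wrongly give 0.5)
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([5.0, 9.0, 7.0])
        assert a[1] == a.mean() and b[2] == b.mean()
        assert icq(pairs(a, b)) == pytest.approx(1 / 3 - 0.5)


finite_channels = arrays(
    np.float64,
    st.integers(4, 32).map(lambda n: (n,)),
    elements=st.integers(0, 255).map(float),
)


@settings(max_examples=150, derandomize=True)
@given(finite_channels, finite_channels)
def test_coefficient_ranges_and_symmetry(a, b):
    """Fuzzed range + symmetry invariants on arbitrary 8-bit channels."""
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    try:
        r_ab, r_ba = pearson(pairs(a, b)), pearson(pairs(b, a))
        q_ab, q_ba = icq(pairs(a, b)), icq(pairs(b, a))
    except ConstantChannelError:
        return
    assert -1 - 1e-12 <= r_ab <= 1 + 1e-12
    assert -0.5 <= q_ab <= 0.5
    assert r_ab == pytest.approx(r_ba, abs=1e-12)
    assert q_ab == q_ba
    try:
        m1, m2 = manders(pairs(a, b))
        m1r, m2r = manders(pairs(b, a))
    except ZeroSignalError:
        return
    assert 0 <= m1 <= 1 and 0 <= m2 <= 1
    assert m1 == pytest.approx(m2r) and m2 == pytest.approx(m1r)


@settings(max_examples=100, derandomize=True)
@given(
    finite_channels,
    st.floats(0.25, 4.0),
    st.floats(0.0, 50.0),
)
def test_pearson_and_icq_invariant_to_positive_affine_rescale(a, scale, shift):
    rng = np.random.default_rng(7)
    b = rng.integers(0, 256, size=len(a)).astype(float)
    try:
        r0, q0 = pearson(pairs(a, b)), icq(pairs(a, b))
    except ConstantChannelError:
        return
    r1 = pearson(pairs(a * scale + shift, b))
    q1 = icq(pairs(a * scale + shift, b))
    assert r1 == pytest.approx(r0, abs=1e-9)
    assert q1 == q0


@pytest.mark.parametrize("seed", range(20))
def test_coefficients_match_bruteforce_on_random_vectors(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 64))
    a = rng.integers(0, 256, n).astype(float)
    b = rng.integers(0, 256, n).astype(float)
    p = pairs(a, b)
    assert pearson(p) == pytest.approx(brute_pearson(a, b), abs=1e-12)
    assert icq(p) == pytest.approx(brute_icq(a, b), abs=1e-12)
    if a.sum() > 0 and b.sum() > 0:
        m = manders(p)
        bm = brute_manders(a, b)
        assert m[0] == pytest.approx(bm[0], abs=1e-12)
        assert m[1] == pytest.approx(bm[1], abs=1e-12)


class TestPDMImage:
    def full_roi(self, shape):
        h, w = shape
        return RegionOfInterest(
            "polygon", [[-0.5, -0.5], [w - 0.5, -0.5], [w - 0.5, h - 0.5], [-0.5, h - 0.5]]
        )

    def test_identical_channels_mask_is_above_mean_pixels(self, rng):
        px = rng.integers(0, 256, (9, 9)).astype(np.uint8)
        img = ChannelImage(px)
        pdm = pdm_image(img, img, self.full_roi(px.shape))
        assert (pdm.positive_mask == (px > px.mean())).all()

    def test_pdm_sum_equals_n_times_population_covariance(self, rng):
        a = ChannelImage(rng.integers(0, 256, (8, 10)).astype(np.uint8))
        b = ChannelImage(rng.integers(0, 256, (8, 10)).astype(np.uint8))
        pdm = pdm_image(a, b, self.full_roi((8, 10)))
        n = pdm.n_pixels
        cov_pop = np.cov(a.pixels.ravel(), b.pixels.ravel(), ddof=0)[0, 1]
        assert np.nansum(pdm.pdm) == pytest.approx(n * cov_pop, rel=1e-10)

    def test_positive_mask_excludes_below_mean_products(self, rng):
        a = ChannelImage(rng.integers(0, 256, (8, 10)).astype(np.uint8))
        b = ChannelImage(rng.integers(0, 256, (8, 10)).astype(np.uint8))
        pdm = pdm_image(a, b, self.full_roi((8, 10)))
        # (-x-) pixels have positive PDM but sit below both means: excluded
        assert (pdm.pdm[pdm.positive_mask] > 0).all()
        both_below = (
            pdm.roi_support
            & (a.pixels < pdm.mean_a)
            & (b.pixels < pdm.mean_b)
        )
        assert not (pdm.positive_mask & both_below).any()

    def test_independent_noise_mean_pdm_near_zero(self):
        rng = np.random.default_rng(42)
        a = ChannelImage(rng.integers(0, 256, (64, 64)).astype(np.uint8))
        b = ChannelImage(rng.integers(0, 256, (64, 64)).astype(np.uint8))
        pdm = pdm_image(a, b, self.full_roi((64, 64)))
        # mean PDM is the population covariance; ~N(0, var/sqrt(N)) here
        assert abs(np.nanmean(pdm.pdm)) < 3 * (255**2 / 12) / np.sqrt(64 * 64)


class TestColocSummaryOnScenes:
    def test_independent_sparse_scenes_have_null_icq_before_subtraction(self):
        """With no co-positioning, ICQ over the dendrite ROI is ~0 (random
        staining) as long as the zero-zero background pixels still carry
        independent noise (i.e. before background subtraction)."""
        from punctacoloc import SceneParams, generate_punctate_pair, scene_rois

        sparse = dict(
            image_height_px=64, image_width_px=4580,
            dendrite_path=[[18.0, 32.0], [4563.0, 32.0]],
            cluster_density_per_um=0.03, amplitude_sd=20.0, psf_sigma_px=1.2,
            background_level=8.0,
        )
        vals = []
        for seed in range(20):
            scene = generate_punctate_pair(
                SceneParams(coloc_fraction=0.0, seed=seed, **sparse)
            )
            roi, _ = scene_rois(scene, line_width_px=10.0)
            vals.append(coloc_summary(scene.channel_a, scene.channel_b, roi).icq)
        assert abs(np.mean(vals)) < 0.05

    def test_fully_colocalized_scene_scores_high(self):
        """High-SNR fully co-positioned puncta: Rr > 0.9 and ICQ > 0.3
        through the full preprocessing chain."""
        from punctacoloc import SceneParams, generate_punctate_pair, scene_rois

        scene = generate_punctate_pair(SceneParams(coloc_fraction=1.0, seed=3))
        roi, bg = scene_rois(scene)
        res = coloc_summary(scene.channel_a, scene.channel_b, roi, bg, k_sd=2.0)
        assert res.pearson_rr > 0.9
        assert res.icq > 0.3
        assert res.indicates_colocalization


class TestColocSummary:
    def test_summary_flags_conventional_pearson_cutoff(self, rng):
        h, w = 16, 16
        a = rng.integers(1, 256, (h, w)).astype(np.uint8)
        img_a = ChannelImage(a)
        roi = RegionOfInterest(
            "polygon", [[-0.5, -0.5], [w - 0.5, -0.5], [w - 0.5, h - 0.5], [-0.5, h - 0.5]]
        )
        res = coloc_summary(img_a, img_a, roi)
        assert res.pearson_rr == pytest.approx(1.0)
        assert res.indicates_colocalization
        b = ChannelImage((255 - a).astype(np.uint8))
        assert not coloc_summary(img_a, b, roi).indicates_colocalization

    def test_summary_coefficients_share_the_same_pixel_set(self, rng):
        h, w = 12, 12
        a = ChannelImage(rng.integers(0, 256, (h, w)).astype(np.uint8))
        b = ChannelImage(rng.integers(0, 256, (h, w)).astype(np.uint8))
        roi = RegionOfInterest("polygon", [[2, 2], [9, 2], [9, 9], [2, 9]])
        res = coloc_summary(a, b, roi)
        assert res.n_pixels == 64
        va = a.pixels[2:10, 2:10].astype(float).ravel()
        vb = b.pixels[2:10, 2:10].astype(float).ravel()
        assert res.pearson_rr == pytest.approx(brute_pearson(va, vb), abs=1e-12)
        assert res.icq == pytest.approx(brute_icq(va, vb), abs=1e-12)
        assert res.mean_a == pytest.approx(va.mean())
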