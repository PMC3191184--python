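import numpy as np
import pytest

from punctacoloc import (
    ChannelImage,
    RegionOfInterest,
    SceneParams,
    convert_to_8bit,
    extract_roi_pixels,
    generate_punctate_pair,
    intensity_profile,
    subtract_background_roi,
)
from punctacoloc.exceptions import EmptyRegionError
from punctacoloc.preprocessing import roi_mask

from .oracles import brute_pixels_in_polygon, brute_pixels_near_polyline


def img16(pixels):
    return ChannelImage(np.asarray(pixels, dtype=np.uint16), bit_depth=16)


class TestConvertTo8Bit:
    def test_endpoints_map_to_0_and_255(self):
        out = convert_to_8bit(img16([[0, 65535], [1000, 2000]]))
        assert out.bit_depth == 8
        assert out.pixels[0, 0] == 0 and out.pixels[0, 1] == 255

    def test_constant_image_maps_to_zero(self):
        out = convert_to_8bit(img16([[500, 500], [500, 500]]))
        assert (out.pixels == 0).all()

    def test_linear_map_rounds_half_up(self):
        # round(255*(612-100)/1024) = round(127.5) -> 128 under half-up
        out = convert_to_8bit(img16([[100, 612], [1124, 100]]))
        assert out.pixels[0, 1] == 128

    def test_8bit_passthrough(self):
        img = ChannelImage(np.array([[5, 9]], dtype=np.uint8))
        assert convert_to_8bit(img) is img

    def test_preserves_intensity_ordering(self, rng):
        px = rng.integers(0, 65536, size=(12, 12)).astype(np.uint16)
        out = convert_to_8bit(img16(px)).pixels
        i = np.argsort(px.ravel(), kind="stable")
        assert (np.diff(out.ravel()[i].astype(int)) >= 0).all()


class TestBackgroundSubtraction:
    def test_constant_roi_threshold_equals_mean(self, square_roi):
        px = np.full((6, 6), 10, dtype=np.uint8)
        out = subtract_background_roi(ChannelImage(px), square_roi, k_sd=2.0)
        assert (out.pixels == 0).all()

    def test_hand_computed_threshold_with_sample_sd(self):
        # ROI pixels {8,10,12}: mean 10, sample SD 2 -> T = 14; 20-14 = 6
        px = np.zeros((4, 6), dtype=np.uint8)
        px[1, 1:4] = [8, 10, 12]
        px[3, 5] = 20
        roi = RegionOfInterest("polygon", [[1, 0.6], [3, 0.6], [3, 1.4], [1, 1.4]])
        out = subtract_background_roi(ChannelImage(px), roi, k_sd=2.0)
        assert out.pixels[3, 5] == 6

    def test_raising_k_sd_never_raises_output(self, rng, square_roi):
        px = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        img = ChannelImage(px)
        prev = subtract_background_roi(img, square_roi, k_sd=0.0).pixels
        for k in (0.5, 1.0, 2.0, 5.0):
            cur = subtract_background_roi(img, square_roi, k_sd=k).pixels
            assert (cur.astype(int) <= prev.astype(int)).all()
            prev = cur

    def test_roi_outside_image_rejected(self):
        img = ChannelImage(np.zeros((8, 8), dtype=np.uint8))
        far = RegionOfInterest("polygon", [[50, 50], [60, 50], [60, 60], [50, 60]])
        with pytest.raises(EmptyRegionError):
            subtract_background_roi(img, far, k_sd=2.0)


class TestExtractRoiPixels:
    def test_axis_aligned_square_selects_nine_pixels(self, square_roi):
        a = ChannelImage(np.arange(36, dtype=np.uint8).reshape(6, 6))
        pairs = extract_roi_pixels(a, a, square_roi)
        assert pairs.n == 9

    def test_unit_width_horizontal_polyline_selects_path_pixels(self):
        a = ChannelImage(np.zeros((10, 12), dtype=np.uint8))
        roi = RegionOfInterest("polyline", [[0, 5], [9, 5]], line_width_px=1)
        pairs = extract_roi_pixels(a, a, roi)
        assert pairs.n == 10
        assert (pairs.pixel_coords[:, 0] == 5).all()

    def test_off_image_roi_is_an_error(self):
        a = ChannelImage(np.zeros((8, 8), dtype=np.uint8))
        roi = RegionOfInterest("polyline", [[100, 100], [120, 100]], line_width_px=1)
        with pytest.raises(EmptyRegionError):
            extract_roi_pixels(a, a, roi)

    def test_identical_coordinates_for_both_channels_row_major(self, rng, square_roi):
        a = ChannelImage(rng.integers(0, 256, (6, 6)).astype(np.uint8))
        b = ChannelImage(rng.integers(0, 256, (6, 6)).astype(np.uint8))
        pairs = extract_roi_pixels(a, b, square_roi)
        rc = pairs.pixel_coords
        order = np.lexsort((rc[:, 1], rc[:, 0]))
        assert (order == np.arange(len(rc))).all()  # row-major
        assert (a.pixels[rc[:, 0], rc[:, 1]] == pairs.a_values).all()
        assert (b.pixels[rc[:, 0], rc[:, 1]] == pairs.b_values).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_polygon_membership_matches_ray_casting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # random convex-ish polygon inside a 16x16 grid
        angles = np.sort(rng.uniform(0, 2 * np.pi, 6))
        radii = rng.uniform(2.5, 6.5, 6)
        verts = np.column_stack([7 + radii * np.cos(angles), 7 + radii * np.sin(angles)])
        mask = roi_mask(RegionOfInterest("polygon", verts), (16, 16))
        got = set(map(tuple, np.argwhere(mask)))
        assert got == set(brute_pixels_in_polygon(verts.tolist(), (16, 16)))

    @pytest.mark.parametrize("seed", [3, 4])
    def test_polyline_membership_matches_distance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        verts = rng.uniform(2, 13, size=(3, 2))
        width = float(rng.integers(1, 5))
        mask = roi_mask(
            RegionOfInterest("polyline", verts, line_width_px=width), (16, 16)
        )
        got = set(map(tuple, np.argwhere(mask)))
        assert got == set(brute_pixels_near_polyline(verts.tolist(), width, (16, 16)))


class TestIntensityProfile:
    def path(self, x0=0, x1=9, y=3):
        return RegionOfInterest("polyline", [[x0, y], [x1, y]])

    def test_constant_image_gives_constant_profile(self):
        img = ChannelImage(np.full((8, 12), 7, dtype=np.uint8))
        assert (intensity_profile(img, self.path()) == 7).all()

    def test_single_bright_pixel_gives_single_peak(self):
        px = np.zeros((8, 12), dtype=np.uint8)
        px[3, 6] = 200
        prof = intensity_profile(ChannelImage(px), self.path())
        assert (prof > 0).sum() == 1 and prof.argmax() == 6

    def test_fully_colocalized_scene_profiles_peak_together(self):
        scene = generate_punctate_pair(
            SceneParams(seed=11, coloc_fraction=1.0, photon_noise=False,
                        read_noise_sd=0.0, background_level=0.0,
                        cluster_density_per_um=0.15, lateral_jitter_px=0.0)
        )
        path = RegionOfInterest("polyline", scene.params.dendrite_path)
        prof_a = intensity_profile(scene.channel_a, path)
        prof_b = intensity_profile(scene.channel_b, path)
        # local maxima of A (well above floor) must coincide with a B peak
        # within 1 sample: co-positioned puncta are offset by <= 1 px
        peaks_a = [
            i for i in range(1, len(prof_a) - 1)
            if prof_a[i] >= prof_a[i - 1] and prof_a[i] >= prof_a[i + 1] and prof_a[i] > 50
        ]
        assert peaks_a
        for i in peaks_a:
            window = prof_b[max(i - 2, 0): i + 3]
            assert window.max() > 50
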