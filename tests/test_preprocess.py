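"""Preprocessing chain: per-stage behaviour, ordering, recovery."""

import numpy as np
import pytest
from scipy import ndimage

from mandifrac.errors import (
    DimensionError,
    InvalidParameterError,
    PipelineOrderError,
    RoiBoundsError,
)
from mandifrac.fractal import box_count, fractal_dimension
from mandifrac.preprocess import (
    BinaryPatch,
    GreyPatch,
    RoiSpec,
    Stage,
    binarize,
    crop_roi,
    gaussian_background,
    invert,
    morpho_clean,
    preprocess,
    skeletonize,
    subtract_offset,
)
from mandifrac.synthetic import SynthParams, make_grey_patch


def grey(arr):
    return GreyPatch(np.asarray(arr, dtype=np.uint8))


class TestCropRoi:
    def test_top_left_block(self):
        image = np.arange(100 * 100, dtype=np.int32).reshape(100, 100) % 256
        roi = RoiSpec("anterior", "right", (0, 0), 64)
        out = crop_roi(image.astype(np.uint8), roi)
        assert np.array_equal(out.pixels, image.astype(np.uint8)[:64, :64])

    def test_bottom_right_block(self):
        image = np.zeros((100, 100), dtype=np.uint8)
        image[36:, 36:] = 7
        out = crop_roi(image, RoiSpec("molar", "left", (36, 36), 64))
        assert (out.pixels == 7).all()

    def test_out_of_bounds_names_coordinate(self):
        image = np.zeros((100, 100), dtype=np.uint8)
        with pytest.raises(RoiBoundsError, match="114"):
            crop_roi(image, RoiSpec("premolar", "right", (50, 50), 64))


class TestGaussianBackground:
    def test_constant_patch_maps_to_same_constant(self):
        out = gaussian_background(grey(np.full((64, 64), 100)), sigma=35)
        assert np.allclose(out, 100.0)

    def test_impulse_mass_conserved_under_reflection(self):
        patch = np.zeros((64, 64), dtype=np.uint8)
        patch[32, 32] = 200
        out = gaussian_background(grey(patch), sigma=5)
        assert out.sum() == pytest.approx(200.0, rel=1e-9)

    def test_smoothing_contracts_the_range(self, rng):
        noise = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        out = gaussian_background(grey(noise), sigma=35)
        assert out.max() - out.min() < noise.max() - noise.min()

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            gaussian_background(grey(np.zeros((8, 8))), sigma=0)


class TestSubtractOffset:
    def test_constant_minus_own_blur_gives_flat_128(self):
        patch = grey(np.full((64, 64), 77))
        out = subtract_offset(patch, gaussian_background(patch), offset=128)
        assert (out.pixels == 128).all()

    def test_pixel_arithmetic_and_clamping(self):
        patch = grey([[200, 0]])
        out = subtract_offset(patch, np.array([[150.0, 200.0]]))
        assert out.pixels[0, 0] == 178  # 200 - 150 + 128
        assert out.pixels[0, 1] == 0  # 0 - 200 + 128 clamps at 0

    def test_shape_mismatch_raises(self):
        with pytest.raises(DimensionError):
            subtract_offset(grey(np.zeros((4, 4))), np.zeros((5, 5)))


class TestBinarize:
    @pytest.mark.parametrize("value,white", [(127, False), (128, True), (129, True)])
    def test_threshold_rule_with_ties_white(self, value, white):
        out = binarize(grey(np.full((8, 8), value)))
        assert out.pixels.all() == white or (not out.pixels.any()) == (not white)
        assert out.stage == Stage.THRESHOLDED


class TestMorphoClean:
    def test_all_white_is_preserved(self):
        out = morpho_clean(binarize(grey(np.full((16, 16), 255))))
        assert out.pixels.all()
        assert out.stage == Stage.CLEANED

    def test_isolated_speckle_removed(self):
        arr = np.zeros((16, 16), dtype=np.uint8)
        arr[8, 8] = 255
        out = morpho_clean(binarize(grey(arr)))
        assert not out.pixels.any()

    def test_solid_block_matches_direct_opening(self):
        arr = np.zeros((32, 32), dtype=np.uint8)
        arr[10:20, 10:20] = 255
        out = morpho_clean(binarize(grey(arr)))
        se = np.ones((3, 3), bool)
        oracle = ndimage.binary_dilation(
            ndimage.binary_erosion(arr > 0, se, border_value=1),
            se,
            border_value=0,
        )
        assert np.array_equal(out.pixels, oracle)
        assert out.pixels[10:20, 10:20].sum() >= 8 * 8  # interior intact


class TestInvert:
    def test_involution_and_count_complement(self):
        pattern = BinaryPatch(
            np.eye(16, dtype=bool), stage=Stage.CLEANED
        )
        flipped = invert(pattern)
        assert flipped.pixels.sum() == 16 * 16 - 16
        back = invert(BinaryPatch(flipped.pixels, stage=Stage.CLEANED))
        assert np.array_equal(back.pixels, pattern.pixels)


class TestSkeletonize:
    def test_thick_bar_thins_to_single_pixel_line(self):
        arr = np.zeros((32, 32), dtype=bool)
        arr[15:18, 4:28] = True  # 3 px wide, 24 px long bar
        out = skeletonize(BinaryPatch(arr, stage=Stage.INVERTED))
        assert out.stage == Stage.SKELETONIZED
        assert (out.pixels.sum(axis=0) <= 1).all()
        assert abs(int(out.pixels.sum()) - 24) <= 2

    def test_skeleton_is_subset_of_input(self, rng):
        arr = rng.random((64, 64)) < 0.6
        out = skeletonize(BinaryPatch(arr, stage=Stage.INVERTED))
        assert not (out.pixels & ~arr).any()

    def test_no_2x2_foreground_block(self, rng):
        arr = rng.random((64, 64)) < 0.7
        sk = skeletonize(BinaryPatch(arr, stage=Stage.INVERTED)).pixels
        blocks = sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]
        assert not blocks.any()

    def test_idempotent(self, rng):
        arr = rng.random((64, 64)) < 0.6
        once = skeletonize(BinaryPatch(arr, stage=Stage.INVERTED)).pixels
        twice = skeletonize(BinaryPatch(once, stage=Stage.INVERTED)).pixels
        assert np.array_equal(once, twice)

    def test_empty_pattern_stays_empty(self):
        out = skeletonize(
            BinaryPatch(np.zeros((16, 16), bool), stage=Stage.INVERTED)
        )
        assert not out.pixels.any()


class TestStageOrdering:
    @pytest.mark.parametrize(
        "op,wrong_stage",
        [
            (morpho_clean, Stage.CLEANED),
            (morpho_clean, Stage.SKELETONIZED),
            (invert, Stage.THRESHOLDED),
            (skeletonize, Stage.CLEANED),
            (skeletonize, Stage.THRESHOLDED),
        ],
    )
    def test_out_of_order_calls_fail(self, op, wrong_stage):
        patch = BinaryPatch(np.ones((8, 8), bool), stage=wrong_stage)
        with pytest.raises(PipelineOrderError):
            op(patch)


class TestFullChain:
    def test_constant_patch_flagged_degenerate(self):
        result = preprocess(grey(np.full((64, 64), 140)))
        assert result.degenerate

    def test_foreground_fractions_logged_for_all_stages(self):
        patch = make_grey_patch(SynthParams(seed=4, texture_model="strut_lattice"))
        result = preprocess(patch)
        assert set(result.foreground_fractions) == {
            "thresholded",
            "cleaned",
            "inverted",
            "skeletonized",
        }
        assert not result.degenerate

    @pytest.mark.parametrize("amplitude", [0.0, 60.0])
    def test_recovered_skeleton_fd_tracks_clean_pattern(self, amplitude):
        """The chain recovers the texture: the skeleton's FD stays within
        0.15 of the clean pattern's skeleton FD, with or without an
        illumination gradient (the sigma=35 step removes it)."""
        patch = make_grey_patch(
            SynthParams(
                seed=11,
                texture_model="ifs_fractal",
                illumination_amplitude=amplitude,
                noise_sd=2.0,
            )
        )
        recovered = preprocess(patch)
        assert not recovered.degenerate
        clean_skeleton = skeletonize(
            BinaryPatch(patch.clean_pattern, stage=Stage.INVERTED)
        )
        fd_rec = fractal_dimension(box_count(recovered.skeleton, n_offsets=1)).fd
        fd_clean = fractal_dimension(box_count(clean_skeleton, n_offsets=1)).fd
        assert abs(fd_rec - fd_clean) < 0.15
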