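import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rootridge.imaging import Frame
from rootridge.segmentation import (
    LabelRegion,
    SegmentationParams,
    build_label_mask,
    combine_masks,
    compute_blueness,
    compute_blur_mask,
    get_stem_mask,
    refine_root_mask,
    segment_foreground,
    segment_root_system,
)


def _rgb(r, g, b, shape=(4, 4)):
    px = np.zeros(shape + (3,), dtype=np.uint8)
    px[:, :, 0], px[:, :, 1], px[:, :, 2] = r, g, b
    return px


class TestBlueness:
    @pytest.mark.parametrize(
        "rgb,beta",
        [((0, 0, 0), 0.0), ((0, 0, 255), 765.0), ((255, 255, 255), -102.0)],
    )
    def test_channel_weights(self, rgb, beta):
        px = _rgb(*rgb)
        px[0, 0] = (0, 0, 255)  # keep the normalization well-defined
        bl = compute_blueness(px)
        assert bl.beta[1, 1] == pytest.approx(beta)

    def test_normalization_uses_per_frame_max(self):
        px = _rgb(0, 0, 128)
        bl = compute_blueness(px)
        assert np.allclose(bl.beta_norm, 255.0)

    def test_degenerate_no_blue_warns_and_fails_open(self):
        px = _rgb(200, 10, 0)  # beta < 0 everywhere
        with pytest.warns(UserWarning, match="blueness"):
            bl = compute_blueness(px)
        assert bl.degenerate
        F = segment_foreground(bl, T_beta=128)
        assert F.all()  # whole frame becomes foreground


class TestForeground:
    def test_saturated_blue_is_background(self):
        bl = compute_blueness(_rgb(0, 0, 255))
        assert not segment_foreground(bl, 128).any()

    def test_threshold_semantics(self):
        bl = compute_blueness(_rgb(0, 0, 255))
        bl.beta_norm[1, 1] = 40.0  # a root-gray pixel
        F = segment_foreground(bl, 128)
        assert F[1, 1] and F.sum() == 1

    def test_matches_bruteforce_pixelwise(self, rng):
        beta_norm = rng.uniform(-50, 260, size=(13, 17))
        bl = compute_blueness(_rgb(0, 0, 255, shape=(13, 17)))
        bl.beta_norm = beta_norm
        F = segment_foreground(bl, 128)
        expected = np.array(
            [[beta_norm[i, j] < 128 for j in range(17)] for i in range(13)]
        )
        assert np.array_equal(F, expected)

    @given(t1=st.floats(0, 255), t2=st.floats(0, 255))
    @settings(deadline=None, max_examples=30)
    def test_monotone_in_threshold(self, t1, t2):
        rng = np.random.default_rng(0)
        bl = compute_blueness(_rgb(0, 0, 255, shape=(8, 8)))
        bl.beta_norm = rng.uniform(0, 255, size=(8, 8))
        lo, hi = sorted([t1, t2])
        assert not (segment_foreground(bl, lo) & ~segment_foreground(bl, hi)).any()


class TestBlurMask:
    def test_sharp_bar_is_covered(self, horizontal_bar):
        img = horizontal_bar(full_width=10)
        C = compute_blur_mask(img, blur_dilation_px=5)
        assert C[45:55, 50:150].all()  # bar interior within 5 px of its edges

    def test_constant_image_has_no_edges(self):
        assert not compute_blur_mask(np.full((50, 50), 80.0)).any()

    def test_heavily_blurred_bar_excluded(self, horizontal_bar):
        from scipy.ndimage import uniform_filter

        img = uniform_filter(horizontal_bar(full_width=6), size=41)
        C = compute_blur_mask(img, canny_low=50, canny_high=150)
        assert not C[45:55, 80:120].any()


class TestLabelMask:
    def test_empty_regions_all_ones(self):
        assert build_label_mask((10, 10), []).all()

    def test_single_rectangle_area(self):
        L = build_label_mask((50, 50), [LabelRegion(5, 7, 10, 10)])
        assert (~L).sum() == 100

    def test_overlapping_rectangles_union(self, rng):
        regs = [LabelRegion(2, 3, 8, 6), LabelRegion(6, 5, 9, 9)]
        L = build_label_mask((30, 40), regs)
        brute = np.zeros((30, 40), dtype=bool)
        for r in regs:
            for y in range(r.y, min(30, r.y + r.h)):
                for x in range(r.x, min(40, r.x + r.w)):
                    brute[y, x] = True
        assert np.array_equal(~L, brute)

    def test_out_of_bounds_clipped(self):
        L = build_label_mask((10, 10), [LabelRegion(8, 8, 10, 10)])
        assert (~L).sum() == 4


class TestStemMask:
    def test_none_gives_all_ones(self):
        assert get_stem_mask((5, 5), None).all()

    def test_inversion_count(self, rng):
        stem = np.zeros((20, 20), dtype=np.uint8)
        idx = rng.choice(400, size=50, replace=False)
        stem.flat[idx] = 1
        S = get_stem_mask((20, 20), stem)
        assert (~S).sum() == 50

    def test_shape_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="shape"):
            get_stem_mask((5, 5), np.zeros((4, 4)))

    def test_empty_stem_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            S = get_stem_mask((5, 5), np.zeros((5, 5)))
        assert S.all()


class TestCombineRefine:
    def test_identity(self):
        ones = np.ones((6, 6), dtype=bool)
        assert combine_masks(ones, ones, ones, ones).all()

    def test_absorbing_zero(self):
        ones = np.ones((6, 6), dtype=bool)
        S = ones.copy()
        S[2, 3] = False
        M = combine_masks(ones, S, ones, ones)
        assert not M[2, 3] and M.sum() == 35

    def test_random_masks_match_bruteforce(self, rng):
        masks = [rng.random((9, 9)) > 0.5 for _ in range(4)]
        M = combine_masks(*masks)
        brute = np.array(
            [
                [all(m[i, j] for m in masks) for j in range(9)]
                for i in range(9)
            ]
        )
        assert np.array_equal(M, brute)

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError):
            combine_masks(
                np.ones((4, 4), bool),
                np.ones((5, 5), bool),
                np.ones((4, 4), bool),
                np.ones((4, 4), bool),
            )

    def test_refine_identity_parameters(self, rng):
        M = rng.random((20, 20)) > 0.4
        assert np.array_equal(refine_root_mask(M, 0, 0), M)

    def test_small_fragment_removed(self):
        M = np.zeros((20, 20), dtype=bool)
        M[5:8, 5] = True  # 3-px blob
        M[12:19, 10:17] = True  # large block survives
        RS = refine_root_mask(M, theta_px=0, T_F=10)
        assert not RS[5:8, 5].any()
        assert RS[12:19, 10:17].all()

    def test_erosion_of_square_by_disk(self):
        M = np.zeros((40, 40), dtype=bool)
        M[10:30, 10:30] = True
        RS = refine_root_mask(M, theta_px=2, T_F=0)
        assert RS[12:28, 12:28].all()
        assert RS.sum() == 16 * 16

    @given(
        M=hnp.arrays(bool, (15, 15)),
        t1=st.integers(0, 3),
        t2=st.integers(0, 3),
    )
    @settings(deadline=None, max_examples=30)
    def test_erosion_monotone_in_theta(self, M, t1, t2):
        lo, hi = sorted([t1, t2])
        assert refine_root_mask(M, hi, 0).sum() <= refine_root_mask(M, lo, 0).sum()


class TestMaskAlgebraInvariants:
    def test_M_subset_of_factors_and_RS_subset_of_M(self, rng):
        px = rng.integers(0, 256, size=(60, 60, 3), dtype=np.uint8)
        px[:20] = (20, 40, 210)  # some blue background
        frame = Frame(px)
        params = SegmentationParams(theta_px=1, T_F=5)
        ms = segment_root_system(frame, params)
        for factor in (ms.F, ms.S, ms.L, ms.C):
            assert not (ms.M & ~factor).any()
        assert not (ms.RS & ~ms.M).any()

    def test_combine_idempotent_with_ones(self, rng):
        M = rng.random((12, 12)) > 0.5
        ones = np.ones_like(M)
        assert np.array_equal(combine_masks(M, ones, ones, ones), M)


def test_save_masks_writes_all_stage_pngs(tmp_path, rng):
    import imageio.v3 as iio

    from rootridge.segmentation import save_masks

    px = rng.integers(0, 256, size=(20, 20, 3), dtype=np.uint8)
    px[:8] = (20, 40, 210)
    ms = segment_root_system(Frame(px), SegmentationParams())
    save_masks(ms, tmp_path)
    for name in ("F", "S", "L", "C", "M", "RS"):
        img = iio.imread(tmp_path / f"{name}.png")
        assert img.shape == (20, 20)
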