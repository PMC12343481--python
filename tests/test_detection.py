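import numpy as np
import pytest
from scipy.spatial import ConvexHull

from pocketcav.detection import (
    DetectionParams,
    FrameSequence,
    areas,
    convex_hull_fill,
    detect_pb,
    detect_sc,
    morph_close,
    morph_open,
    segment_sequence,
    subtract_background,
    threshold_fraction,
)
from pocketcav.phantoms import PhantomConfig, make_cavitation_sequence
from pocketcav.physics import ConfigurationError


class TestSubtractBackground:
    def test_identical_frames_give_zero(self, rng):
        frame = rng.uniform(0, 1, (16, 16))
        assert not subtract_background(frame, frame).any()

    def test_single_bright_pixel(self):
        background = np.full((8, 8), 0.2)
        frame = background.copy()
        frame[3, 4] = 0.9
        diff = subtract_background(frame, background)
        assert diff[3, 4] == pytest.approx(0.7)
        assert diff.sum() == pytest.approx(0.7)

    def test_clip_mode_discards_darkening(self):
        frame = np.full((4, 4), 0.1)
        background = np.full((4, 4), 0.5)
        assert not subtract_background(frame, background, "clip").any()
        assert subtract_background(frame, background, "abs")[0, 0] == pytest.approx(0.4)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((4, 4)), np.zeros((5, 4)))

    def test_support_covers_truth_on_noise_free_phantom(self, phantom_cfg, detect_params):
        seq, truth = make_cavitation_sequence(phantom_cfg)
        i = int(np.argmax(truth.pb_area_mm2))
        diff = subtract_background(seq.frames[i], seq.frames[0])
        support = diff > 0
        features = truth.pb_masks[i] | truth.sc_masks[i]
        # the fiber-tip stripe occludes part of the bubble top by design
        stripe = np.zeros_like(support)
        c0 = phantom_cfg.ft_column_px - phantom_cfg.ft_width_px // 2
        stripe[: phantom_cfg.ft_tip_row_px, c0 : c0 + phantom_cfg.ft_width_px] = True
        assert (features & ~stripe & ~support).sum() == 0


class TestThresholdFraction:
    def test_fraction_of_maximum(self):
        image = np.array([[0.8, 0.61], [0.59, 0.1]])
        mask = threshold_fraction(image, 0.75)  # cut at 0.6
        assert mask.tolist() == [[True, True], [False, False]]

    def test_constant_nonzero_image_selects_everything(self):
        assert threshold_fraction(np.full((5, 5), 0.3), 0.5).all()

    def test_all_zero_image_selects_nothing(self):
        assert not threshold_fraction(np.zeros((5, 5)), 0.5).any()

    def test_matches_per_pixel_comparison_oracle(self, rng):
        image = rng.uniform(0, 1, (12, 17))
        fraction = 0.62
        expected = np.empty(image.shape, dtype=bool)
        cut = fraction * image.max()
        for r in range(image.shape[0]):
            for c in range(image.shape[1]):
                expected[r, c] = image[r, c] >= cut
        assert np.array_equal(threshold_fraction(image, fraction), expected)

    def test_raising_fraction_never_grows_the_mask(self, rng):
        image = rng.uniform(0, 1, (32, 32))
        counts = [threshold_fraction(image, f).sum() for f in np.linspace(0.05, 0.95, 19)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_rejects_fraction_outside_open_interval(self, fraction):
        with pytest.raises(ValueError):
            threshold_fraction(np.ones((2, 2)), fraction)


def _disk_offsets(radius):
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def _erode_oracle(mask, radius):
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            out[r, c] = all(
                0 <= r + dr < h and 0 <= c + dc < w and mask[r + dr, c + dc]
                for dr, dc in _disk_offsets(radius)
            )
    return out


def _dilate_oracle(mask, radius):
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r, c in zip(*np.nonzero(mask)):
        for dr, dc in _disk_offsets(radius):
            if 0 <= r + dr < h and 0 <= c + dc < w:
                out[r + dr, c + dc] = True
    return out


class TestMorphology:
    def test_opening_removes_isolated_pixel(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 10] = True
        assert not morph_open(mask, 5).any()

    def test_opening_is_idempotent(self):
        mask = np.zeros((70, 70), dtype=bool)
        mask[10:60, 10:60] = True
        once = morph_open(mask, 5)
        assert np.array_equal(morph_open(once, 5), once)

    def test_closing_fills_small_hole(self):
        # solid block with a pinhole, away from the image border (pixels
        # outside the image count as background in the set definition)
        mask = np.zeros((40, 40), dtype=bool)
        mask[8:32, 8:32] = True
        mask[19:21, 19:21] = False
        closed = morph_close(mask, 5)
        assert closed[19:21, 19:21].all()
        assert (closed & ~mask).sum() == 4  # only the hole was added

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_matches_set_arithmetic_oracle(self, radius, rng):
        for _ in range(5):
            mask = rng.uniform(0, 1, (20, 20)) < 0.35
            opened = _dilate_oracle(_erode_oracle(mask, radius), radius)
            closed = _erode_oracle(_dilate_oracle(mask, radius), radius)
            assert np.array_equal(morph_open(mask, radius), opened)
            assert np.array_equal(morph_close(mask, radius), closed)

    def test_rejects_radius_below_one(self):
        with pytest.raises(ValueError):
            morph_open(np.ones((4, 4), dtype=bool), 0)


class TestConvexHullFill:
    def test_empty_mask_maps_to_empty(self):
        assert not convex_hull_fill(np.zeros((10, 10), dtype=bool)).any()

    def test_convex_input_nearly_unchanged(self):
        rr, cc = np.ogrid[:40, :40]
        ellipse = ((rr - 20) / 12.0) ** 2 + ((cc - 20) / 8.0) ** 2 <= 1
        hull = convex_hull_fill(ellipse)
        assert (hull & ~ellipse).sum() <= 0.05 * ellipse.sum()
        assert (ellipse & ~hull).sum() == 0

    def test_c_shape_gap_is_sealed_and_hull_contains_input(self):
        rr, cc = np.ogrid[:50, :50]
        d2 = (rr - 25) ** 2 + (cc - 25) ** 2
        annulus = (d2 <= 20**2) & (d2 >= 12**2)
        annulus &= ~((cc > 25) & (np.abs(rr - 25) < 6))  # cut a sector out
        hull = convex_hull_fill(annulus)
        assert (annulus & ~hull).sum() == 0
        assert hull[25, 40]  # the cut sector is covered again
        # oracle: every hull pixel lies inside the convex hull of the points
        points = np.column_stack(np.nonzero(annulus)).astype(float)
        oracle = ConvexHull(points)
        pix = np.column_stack(np.nonzero(hull)).astype(float)
        inside = np.ones(len(pix), dtype=bool)
        for a, b, c in oracle.equations:
            inside &= pix @ np.array([a, b]) + c <= 0.5 + 1e-9
        assert inside.all()

    def test_idempotent(self):
        rr, cc = np.ogrid[:30, :30]
        shape = ((rr - 15) ** 2 + (cc - 12) ** 2 <= 64) | ((rr - 8) ** 2 + (cc - 20) ** 2 <= 25)
        once = convex_hull_fill(shape)
        assert np.array_equal(convex_hull_fill(once), once)


class TestDetectPb:
    def test_background_only_sequence_yields_empty_masks(self, phantom_cfg, detect_params):
        seq, _ = make_cavitation_sequence(phantom_cfg, a_max_mm2=0.0, sc_density_per_mm2=0.0)
        assert not detect_pb(seq, detect_params).any()

    def test_recovers_bubble_with_high_overlap(self, phantom_cfg, detect_params):
        seq, truth = make_cavitation_sequence(phantom_cfg)
        masks = detect_pb(seq, detect_params)
        for i in range(len(seq)):
            if truth.pb_area_mm2[i] < 0.05:
                continue
            inter = (masks[i] & truth.pb_masks[i]).sum()
            dice = 2 * inter / (masks[i].sum() + truth.pb_masks[i].sum())
            assert dice >= 0.9

    def test_hull_seals_fiber_tip_gap_into_one_component(self, phantom_cfg, detect_params):
        from pocketcav.detection import _blur
        from skimage import measure

        seq, truth = make_cavitation_sequence(phantom_cfg)
        i = int(np.argmax(truth.pb_area_mm2))
        # occluded notch: truth pixels hidden behind the fiber-tip stripe
        sub = subtract_background(seq.frames[i], seq.frames[0])
        notch = truth.pb_masks[i] & (sub == 0)
        assert notch.sum() > 0
        # the hull stage recovers the notch that thresholding cannot see
        mask = threshold_fraction(_blur(sub, 3.0), 0.75)
        mask = morph_close(morph_open(mask, 5), 5)
        assert (mask & notch).sum() == 0
        hull = convex_hull_fill(mask)
        # the hull bridges the occluded gap between the two lobes (it cannot
        # recover the notch corners above the detected lobe tops)
        assert (hull & notch).sum() >= 0.3 * notch.sum()
        # and the final PB mask is a single connected region
        masks = detect_pb(seq, detect_params)
        assert measure.label(masks[i], connectivity=2).max() == 1

    def test_rejects_single_frame_sequence(self, detect_params):
        seq = FrameSequence(np.zeros((1, 16, 16)), 10.0, 20.0)
        with pytest.raises(ConfigurationError):
            detect_pb(seq, detect_params)

    def test_final_opening_must_come_after_hull(self, phantom_cfg, detect_params):
        """Regression: swapping the final opening before the hull changes the
        result on the fiber-tip-gap phantom."""
        from pocketcav.detection import _blur

        seq, truth = make_cavitation_sequence(phantom_cfg)
        i = int(np.argmax(truth.pb_area_mm2))
        sub = subtract_background(seq.frames[i], seq.frames[0])
        mask = threshold_fraction(_blur(sub, 3.0), 0.75)
        mask = morph_close(morph_open(mask, 5), 5)
        correct = morph_open(convex_hull_fill(mask), 10)
        swapped = convex_hull_fill(morph_open(mask, 10))
        assert not np.array_equal(correct, swapped)


class TestDetectSc:
    def test_blob_pixels_recovered_inside_band(self, phantom_cfg, detect_params):
        seq, truth = make_cavitation_sequence(phantom_cfg)
        result = segment_sequence(seq, detect_params)
        true_px = truth.sc_masks.sum()
        assert true_px > 0
        recall = (result.sc_masks & truth.sc_masks).sum() / true_px
        assert recall >= 0.8

    def test_no_sc_without_blobs(self, detect_params):
        cfg = PhantomConfig(seed=5, noise_sigma=0.0, n_frames=10)
        seq, _ = make_cavitation_sequence(
            cfg, a_max_mm2=1.8, period_us=50.0, sc_density_per_mm2=0.0
        )
        result = segment_sequence(seq, detect_params)
        assert result.a_sc_mm2.sum() == 0.0

    def test_nothing_reported_above_fiber_tip_row(self, phantom_cfg, detect_params):
        seq, _ = make_cavitation_sequence(phantom_cfg)
        result = segment_sequence(seq, detect_params)
        assert not result.sc_masks[:, : phantom_cfg.ft_tip_row_px, :].any()

    def test_masks_disjoint_from_pb(self, phantom_cfg, detect_params):
        seq, _ = make_cavitation_sequence(phantom_cfg)
        result = segment_sequence(seq, detect_params)
        assert not (result.pb_masks & result.sc_masks).any()

    def test_roi_band_outside_image_raises(self, phantom_cfg):
        params = DetectionParams(ft_tip_row_px=500, ft_column_px=128)
        seq, _ = make_cavitation_sequence(phantom_cfg)
        with pytest.raises(ConfigurationError):
            detect_sc(seq, params, np.zeros(seq.frames.shape, dtype=bool))


class TestAreas:
    def test_hundred_pixels_at_twenty_micron(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask.ravel()[:100] = True
        assert areas(mask, 20.0) == pytest.approx(0.04)

    def test_empty_mask_is_zero(self):
        assert areas(np.zeros((5, 5), dtype=bool), 20.0) == 0.0

    def test_matches_counting_oracle(self, rng):
        masks = rng.uniform(0, 1, (4, 15, 15)) < 0.3
        expected = []
        for mask in masks:
            count = sum(1 for r in range(15) for c in range(15) if mask[r, c])
            expected.append(count * (20.0 / 1000.0) ** 2)
        assert np.allclose(areas(masks, 20.0), expected)

    def test_doubling_pixel_size_quadruples_area(self, rng):
        mask = rng.uniform(0, 1, (10, 10)) < 0.5
        assert areas(mask, 40.0) == pytest.approx(4 * areas(mask, 20.0))

    def test_rejects_non_positive_pixel_size(self):
        with pytest.raises(ConfigurationError):
            areas(np.ones((2, 2), dtype=bool), 0.0)
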