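import numpy as np
import pytest

from retmorph import fractal, io, synthetic
from retmorph.errors import (DiscDetectionError, EmptySegmentationWarning,
                             ParameterError)


def sierpinski(depth=7, cell=4):
    m = np.ones((1, 1), bool)
    for _ in range(depth):
        m = np.block([[m, m], [m, np.zeros_like(m)]])
    return np.kron(m, np.ones((cell, cell), bool))


class TestBoxCounting:
    def test_straight_line_dimension_one(self):
        img = np.zeros((512, 512), bool)
        img[256, :] = True
        res = fractal.box_counting_dimension(img)
        assert res.mean_d == pytest.approx(1.0, abs=0.05)

    def test_filled_square_dimension_two(self):
        res = fractal.box_counting_dimension(np.ones((512, 512), bool))
        assert res.mean_d == pytest.approx(2.0, abs=0.10)

    def test_sierpinski_dimension(self):
        res = fractal.box_counting_dimension(sierpinski())
        assert 1.53 <= res.mean_d <= 1.64  # log 3 / log 2 = 1.585

    def test_translation_invariance(self):
        base = np.zeros((512, 512), bool)
        base[100:356, 100:356] = sierpinski(6, 4)
        shifted = np.roll(base, (37, -21), axis=(0, 1))
        a = fractal.box_counting_dimension(base)
        b = fractal.box_counting_dimension(shifted)
        assert abs(a.mean_d - b.mean_d) <= 0.02

    def test_empty_raster_rejected(self):
        with pytest.raises(ParameterError):
            fractal.box_counting_dimension(np.zeros((64, 64), bool))

    def test_too_small_image_rejected(self):
        with pytest.raises(ParameterError, match="box sizes"):
            fractal.box_counting_dimension(np.ones((20, 20), bool))

    def test_origin_zero_is_deterministic(self):
        img = sierpinski()
        a = fractal.box_counting_dimension(img, n_origins=1)
        b = fractal.box_counting_dimension(img, n_origins=1, seed=999)
        assert a.grid_dims[0] == b.grid_dims[0]


class TestDiscDetection:
    def test_synthetic_disc_geometry(self, default_scene):
        img, truth = default_scene
        rf = io.to_red_free(img).pixels.astype(float)
        disc = fractal.detect_optic_disc(rf)
        err = np.hypot(disc.center[0] - truth.disc_center[0],
                       disc.center[1] - truth.disc_center[1])
        assert err <= 5.0
        assert disc.radius == pytest.approx(truth.disc_radius, rel=0.15)
        assert disc.detection_mode == "auto"

    def test_blank_image_fails_detection(self):
        with pytest.raises(DiscDetectionError):
            fractal.detect_optic_disc(np.full((256, 256), 128.0))

    def test_most_circular_pattern_wins(self):
        rng = np.random.default_rng(0)
        img = 120 + 2 * rng.standard_normal((300, 300))
        rr, cc = np.mgrid[:300, :300]
        img[np.hypot(rr - 90, cc - 90) < 30] += 60          # circular blob
        ell = (((rr - 210) / 55.0) ** 2 + ((cc - 190) / 12.0) ** 2) < 1
        img[ell] += 60                                       # elongated blob
        disc = fractal.detect_optic_disc(img)
        assert np.hypot(disc.center[0] - 90, disc.center[1] - 90) < 8

    def test_radius_zero_rejected_by_invariant(self):
        with pytest.raises(ParameterError):
            fractal.OpticDisc(center=(10, 10), radius=0.0, circularity=0.9)


class TestRoi:
    def test_roi_is_3_5x_disc_diameter(self):
        disc = fractal.OpticDisc(center=(300.0, 300.0), radius=40.0,
                                 circularity=0.9)
        roi = fractal.select_roi(disc, (600, 600))
        assert roi.radius == pytest.approx(140.0)  # 3.5 * diameter / 2
        assert roi.clip_fraction == pytest.approx(0.0, abs=0.01)

    def test_corner_disc_clipped(self):
        disc = fractal.OpticDisc(center=(20.0, 20.0), radius=40.0,
                                 circularity=0.9)
        roi = fractal.select_roi(disc, (600, 600))
        assert roi.clip_fraction > 0.5


class TestBinarizeVasculature:
    def test_outline_contained_in_dilated_mask(self, segmented_scene):
        from scipy import ndimage as ndi
        img, truth, seg = segmented_scene
        rf = io.to_red_free(img).pixels.astype(float)
        roi = np.ones(rf.shape, bool)
        outline = fractal.binarize_vasculature(rf, roi)
        assert outline.sum() < seg.vessel_mask.sum()
        dilated = ndi.binary_dilation(seg.vessel_mask, iterations=2)
        assert (outline & ~dilated).mean() < 0.001

    def test_solid_disk_outline_is_ring(self):
        img = np.full((128, 128), 40.0)
        rr, cc = np.mgrid[:128, :128]
        inside = np.hypot(rr - 64, cc - 64) < 25
        img[inside] = 5.0  # dark disk, vessel polarity
        outline = fractal.binarize_vasculature(img, np.ones_like(inside),
                                               rolling_ball_radius=30,
                                               background_iterations=1)
        d = np.hypot(rr - 64, cc - 64)[outline]
        assert len(d) > 0
        assert d.min() > 20 and d.max() < 27  # 1-px perimeter band

    def test_blank_roi_warns(self):
        img = np.full((128, 128), 90.0)
        with pytest.warns(EmptySegmentationWarning):
            out = fractal.binarize_vasculature(img, np.ones((128, 128), bool),
                                               background_iterations=1)
        assert not out.any()


class TestMeanFractalDimension:
    def test_full_chain_quality(self, default_scene):
        img, truth = default_scene
        rf = io.to_red_free(img).pixels.astype(float)
        res, disc, roi = fractal.mean_fractal_dimension(rf)
        assert 1.0 < res.mean_d < 2.0
        assert (res.r_squared >= 0.95).all()
        assert roi.radius == pytest.approx(2 * 3.5 * disc.radius / 2)

    def test_denser_branching_raises_mean_d(self):
        vals = {}
        for depth in (2, 4):
            spec = synthetic.replace(synthetic.default_image_spec(seed=3),
                                     branching_depth=depth)
            img, _ = synthetic.generate(spec)
            rf = io.to_red_free(img).pixels.astype(float)
            res, _, _ = fractal.mean_fractal_dimension(rf)
            vals[depth] = res.mean_d
        assert vals[4] > vals[2]
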