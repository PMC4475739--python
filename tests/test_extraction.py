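import numpy as np
import pytest
from scipy import ndimage as ndi

from retmorph import extraction
from retmorph.errors import EmptySegmentationWarning, ParameterError
from conftest import draw_bar


def skeleton_is_thin(sk):
    """No 2x2 block of skeleton pixels."""
    return not (sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]).any()


class TestSubtractBackground:
    def test_constant_image_maps_to_zero(self):
        out = extraction.subtract_background(np.full((80, 80), 137.0), radius=10)
        assert np.allclose(out, 0.0)

    def test_iterations_compose(self):
        rng = np.random.default_rng(0)
        img = np.clip(150 + 30 * rng.standard_normal((90, 90)), 0, 255)
        two = extraction.subtract_background(img, radius=8, iterations=2)
        once = extraction.subtract_background(img, radius=8, iterations=1)
        again = extraction.subtract_background(once, radius=8, iterations=1,
                                               dark_features=False)
        np.testing.assert_allclose(two, again)

    def test_vessel_contrast_ratio_increases(self):
        # smooth illumination gradient + one dark vessel stripe
        cols = np.linspace(120, 220, 120)
        img = np.tile(cols, (80, 1))
        img[36:43, :] -= 70.0
        vessel = np.zeros_like(img, bool)
        vessel[36:43, :] = True
        out = extraction.subtract_background(img, radius=10, iterations=1)
        before = abs(img[vessel].mean() - img[~vessel].mean()) / img[~vessel].mean()
        after = out[vessel].mean() / max(out[~vessel].mean(), 1e-6)
        assert after > before

    def test_radius_larger_than_image_rejected(self):
        with pytest.raises(ParameterError):
            extraction.subtract_background(np.zeros((40, 40)), radius=30)


class TestBinarizeAndSkeletonize:
    def test_bar_skeleton_follows_midline(self):
        img, midrow = draw_bar(bar_width=9)
        seg = extraction.binarize_and_skeletonize(img)
        rows, cols = np.nonzero(seg.skeleton)
        assert len(rows) >= 90  # ~100-px path
        interior = (cols > 15) & (cols < 104)  # thinning bends at bar ends
        assert np.abs(rows[interior] - midrow).max() <= 1

    @staticmethod
    def _stroke(img, p0, p1, half_width=3.0, value=200.0):
        """Round-capped thick stroke: pixels within half_width of segment."""
        rr, cc = np.mgrid[: img.shape[0], : img.shape[1]].astype(float)
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        d = p1 - p0
        t = np.clip(((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / (d @ d), 0, 1)
        dist = np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))
        img[dist <= half_width] = value

    def test_y_junction_topology(self):
        img = np.zeros((120, 120))
        self._stroke(img, (100, 60), (55, 60))   # stem
        self._stroke(img, (55, 60), (15, 25))    # left arm
        self._stroke(img, (55, 60), (15, 95))    # right arm
        seg = extraction.binarize_and_skeletonize(img, min_object_px=0)
        sk = seg.skeleton
        nbrs = ndi.convolve(sk.astype(int), np.ones((3, 3), int),
                            mode="constant") - sk
        endpoints = sk & (nbrs == 1)
        branches = sk & (nbrs >= 3)
        assert endpoints.sum() == 3
        _, n_clusters = ndi.label(branches, structure=np.ones((3, 3)))
        assert n_clusters == 1

    def test_blank_image_warns_and_returns_empty(self):
        with pytest.warns(EmptySegmentationWarning):
            seg = extraction.binarize_and_skeletonize(np.zeros((80, 80)))
        assert not seg.vessel_mask.any() and not seg.skeleton.any()

    def test_skeleton_invariants_on_shapes(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            img = np.zeros((100, 100))
            for _ in range(3):
                r, c = rng.integers(10, 80, 2)
                img[r:r + rng.integers(3, 9), c:c + rng.integers(20, 60)] = 200
            seg = extraction.binarize_and_skeletonize(img, min_object_px=0)
            assert (seg.skeleton & ~seg.vessel_mask).sum() == 0
            assert skeleton_is_thin(seg.skeleton)


class TestRemoveLesions:
    def test_bright_blob_on_constant_removed(self):
        img = np.full((80, 80), 100.0)
        img[40:43, 40:43] = 220.0
        cleaned, mask = extraction.remove_lesions(img, radius=4, threshold=30)
        assert mask[40:43, 40:43].all()
        assert np.allclose(cleaned, 100.0)

    def test_constant_image_untouched(self):
        img = np.full((60, 60), 90.0)
        cleaned, mask = extraction.remove_lesions(img)
        assert not mask.any()
        np.testing.assert_array_equal(cleaned, img)

    def test_elongated_stripe_preserved(self):
        img = np.full((80, 120), 150.0)
        img[38:41, 10:110] = 60.0  # 3-px-wide vessel-like stripe
        cleaned, mask = extraction.remove_lesions(img, radius=4, threshold=30)
        assert not mask[38:41, 10:110].any()
        np.testing.assert_array_equal(cleaned[38:41, 10:110],
                                      img[38:41, 10:110])

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(7)
        img = np.clip(140 + 8 * rng.standard_normal((90, 90)), 0, 255)
        img[30:33, 50:53] = 250
        once, _ = extraction.remove_lesions(img)
        twice, mask2 = extraction.remove_lesions(once)
        np.testing.assert_allclose(twice, once)
        assert not mask2.any()


class TestSegmentVessels:
    def test_centerline_recovery_on_synthetic_tree(self, segmented_scene):
        _, truth, seg = segmented_scene
        dist = ndi.distance_transform_edt(~seg.skeleton)
        hits, total = 0, 0
        for pts in truth.centerlines.values():
            ij = np.round(pts).astype(int)
            hits += (dist[ij[:, 0], ij[:, 1]] <= 2).sum()
            total += len(ij)
        assert hits / total >= 0.90

    def test_skeleton_invariants_hold(self, segmented_scene):
        _, _, seg = segmented_scene
        assert (seg.skeleton & ~seg.vessel_mask).sum() == 0
        assert skeleton_is_thin(seg.skeleton)
        assert not (seg.lesion_mask & seg.skeleton).any()

    def test_lesions_removed_from_synthetic_image(self):
        from retmorph import io, synthetic
        spec = synthetic.default_image_spec(seed=4)
        spec = synthetic.replace(
            spec,
            lesions=(synthetic.LesionSpec((120.0, 330.0), 3.5, "bright"),
                     synthetic.LesionSpec((360.0, 330.0), 3.5, "dark")),
        )
        img, truth = synthetic.generate(spec)
        rf = io.to_red_free(img).pixels.astype(float)
        seg = extraction.segment_vessels(rf)
        covered = (seg.lesion_mask & truth.lesion_mask).sum()
        assert covered / truth.lesion_mask.sum() >= 0.8
        assert not (seg.skeleton & truth.lesion_mask).any()
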