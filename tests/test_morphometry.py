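import numpy as np
import pytest

from advafm import morphometry, synthetic
from advafm.morphometry import MorphometryParams
from advafm.synthetic import FibrilFieldSpec, TopographyImage


def _image(heights, nm_per_px=1.0):
    heights = np.asarray(heights, dtype=float)
    return TopographyImage(
        heights=heights,
        nm_per_px=nm_per_px,
        scan_size_nm=nm_per_px * heights.shape[1],
    )


def _rect_mask(shape, r0, r1, c0, c1):
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


class TestParams:
    def test_for_scale_native(self):
        p = MorphometryParams.for_scale(2000.0 / 256.0)
        assert p.seal_px == 0
        assert p.enhance_sigma_px == pytest.approx(2.048)

    def test_for_scale_high_resolution(self):
        p = MorphometryParams.for_scale(2000.0 / 512.0)
        assert p.seal_px == 1
        assert p.enhance_sigma_px == pytest.approx(4.096)

    def test_validate_rejects_bad_ranges(self):
        with pytest.raises(ValueError):
            MorphometryParams(diameter_range_nm=(200.0, 70.0)).validate()
        with pytest.raises(ValueError):
            MorphometryParams(threshold="fixed").validate()


class TestPreprocess:
    def test_flatten_removes_scanline_tilt(self):
        rows = np.arange(64, dtype=float)
        tilted = _image(np.tile(0.5 * rows, (64, 1)))
        flat = morphometry.preprocess(tilted, MorphometryParams(filter_sigma_px=0.0))
        assert np.abs(flat.heights).max() < 1e-9

    def test_filter_scale_too_large(self):
        with pytest.raises(ValueError, match="filter scale too large"):
            morphometry.preprocess(
                _image(np.random.default_rng(0).normal(size=(64, 64))),
                MorphometryParams(enhance_sigma_px=20.0),
            )


class TestBinarize:
    def test_fixed_threshold(self):
        img = _image(np.array([[0.0, 1.0], [2.0, 3.0]]))
        mask = morphometry.binarize(
            img, MorphometryParams(threshold="fixed", threshold_level=1.5)
        )
        assert mask.tolist() == [[False, False], [True, True]]

    def test_degenerate_histogram(self):
        with pytest.raises(ValueError, match="unthresholdable"):
            morphometry.binarize(_image(np.ones((32, 32))), MorphometryParams())

    def test_otsu_separates_two_modes(self, rng):
        h = np.where(rng.random((64, 64)) < 0.5, 0.0, 10.0)
        h += rng.normal(0, 0.1, h.shape)
        mask = morphometry.binarize(_image(h), MorphometryParams())
        assert 0.4 < mask.mean() < 0.6


class TestSkeletonMeasurement:
    def test_rectangle_dimensions_recovered(self):
        # 8 x 16 px rectangle: skeleton geodesic ~ l - w (plus short diagonal
        # end strokes left by thinning), joint solve recovers both dimensions
        mask = _rect_mask((32, 32), 8, 16, 4, 20)
        params = MorphometryParams(seal_px=0, min_area_px=12)
        labels, skeleton = morphometry.seal_and_skeletonize(mask, params)
        df = morphometry.measure_segments(labels, skeleton, 1.0, params)
        assert len(df) == 1
        assert df["dperiod_nm"].iloc[0] == pytest.approx(16.0, abs=2.0)
        assert df["diameter_nm"].iloc[0] == pytest.approx(8.0, abs=1.0)

    def test_axis_assignment_swaps_dimensions(self):
        # rectangle long along x; a vertical fibril axis flips the assignment
        mask = _rect_mask((32, 32), 8, 16, 4, 20)
        params = MorphometryParams(seal_px=0, min_area_px=12)
        labels, skeleton = morphometry.seal_and_skeletonize(mask, params)
        df = morphometry.measure_segments(labels, skeleton, 1.0, params, axis_deg=90.0)
        assert df["diameter_nm"].iloc[0] == pytest.approx(16.0, abs=2.0)

    def test_dperiod_from_neighbor_spacing(self):
        # two collinear rectangles 20 px apart centre to centre: the left one
        # gets its D-period from the spacing, the right one (no downstream
        # neighbour) keeps the rectangle-length fallback
        mask = _rect_mask((32, 48), 8, 16, 4, 20) | _rect_mask((32, 48), 8, 16, 24, 40)
        params = MorphometryParams(seal_px=0, min_area_px=12)
        labels, skeleton = morphometry.seal_and_skeletonize(mask, params)
        df = morphometry.measure_segments(labels, skeleton, 1.0, params, axis_deg=0.0)
        assert len(df) == 2
        left = df.loc[df["centroid_x_px"].idxmin()]
        assert left["dperiod_nm"] == pytest.approx(20.0, abs=0.5)

    def test_min_area_filter(self):
        mask = _rect_mask((32, 32), 8, 10, 4, 7)  # 6 px blob
        labels, _ = morphometry.seal_and_skeletonize(
            mask, MorphometryParams(min_area_px=12)
        )
        assert labels.max() == 0

    def test_degenerate_component_flagged_invalid(self):
        mask = _rect_mask((32, 32), 8, 12, 4, 8)  # 4 x 4 square: point skeleton
        params = MorphometryParams(seal_px=0, min_area_px=4)
        labels, skeleton = morphometry.seal_and_skeletonize(mask, params)
        df = morphometry.measure_segments(labels, skeleton, 1.0, params)
        assert not df["valid"].any()


class TestImageLevel:
    def test_dominant_orientation(self, rendered_image):
        image, _ = rendered_image
        angle = morphometry.dominant_orientation(image)
        assert abs(angle - 30.0) < 6.0

    def test_analyze_image_recovers_scales(self, rendered_image):
        image, truth = rendered_image
        segments, qc = morphometry.analyze_image(image)
        assert qc.usable
        valid = segments[segments["valid"]]
        vis = truth[truth["visible"]]
        diam_err = valid["diameter_nm"].median() / vis["diameter_nm"].mean() - 1
        dper_err = valid["dperiod_nm"].median() / vis["dperiod_nm"].mean() - 1
        assert abs(diam_err) < 0.15
        assert abs(dper_err) < 0.05

    def test_qc_flags_sparse_mask(self):
        segments = morphometry.measure_segments(
            np.zeros((32, 32), dtype=int), np.zeros((32, 32), dtype=bool), 1.0
        )
        qc = morphometry.image_qc(segments, np.zeros((32, 32), dtype=bool))
        assert not qc.usable
        assert qc.n_components == 0
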