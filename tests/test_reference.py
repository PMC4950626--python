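import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import iphquant as iq
from conftest import brute_circle_mask, brute_polygon_mask, make_slice, square, star_polygon


class TestRasterizeCircle:
    def test_matches_brute_force_and_analytic_area(self):
        s = make_slice(np.zeros((101, 101)))
        mask = iq.rasterize_circle((50.0, 50.0), 40.0, s)
        assert np.array_equal(mask, brute_circle_mask((50.0, 50.0), 40.0, s))
        assert mask.sum() == pytest.approx(np.pi * 20.0**2, rel=0.015)

    def test_subpixel_circle_is_single_pixel(self):
        s = make_slice(np.zeros((10, 10)))
        mask = iq.rasterize_circle((4.0, 7.0), 0.5, s)
        assert mask.sum() == 1 and mask[7, 4]

    def test_far_center_gives_empty_mask(self):
        s = make_slice(np.zeros((10, 10)))
        assert not iq.rasterize_circle((1000.0, 1000.0), 40.0, s).any()
        # partially outside: distance condition still decides
        edge = iq.rasterize_circle((-2.0, 5.0), 10.0, s)
        assert edge.any()
        assert np.array_equal(edge, brute_circle_mask((-2.0, 5.0), 10.0, s))


class TestRasterizePolygon:
    def test_axis_aligned_square_covers_16_pixels(self):
        s = make_slice(np.zeros((8, 8)))
        mask = iq.rasterize_polygon(square(1.5, 1.5, 5.5, 5.5), s)
        assert mask.sum() == 16
        assert mask[2:6, 2:6].all()

    def test_random_star_polygons_match_brute_force(self):
        rng = np.random.default_rng(11)
        s = make_slice(np.zeros((64, 64)), spacing=(0.7, 1.1))
        for _ in range(10):
            poly = star_polygon(rng, center=rng.uniform(10, 50, size=2))
            assert np.array_equal(iq.rasterize_polygon(poly, s), brute_polygon_mask(poly, s))

    def test_sliver_triangle_between_centers_is_empty(self):
        s = make_slice(np.zeros((10, 10)))
        tri = np.array([[1.1, 1.1], [1.9, 1.1], [1.5, 1.9]])
        assert not iq.rasterize_polygon(tri, s).any()

    def test_degenerate_polygon_rejected(self):
        s = make_slice(np.zeros((10, 10)))
        with pytest.raises(iq.ValidationError):
            iq.rasterize_polygon(np.array([[0, 0], [1, 1], [2, 2]]), s)

    def test_nested_polygons_give_nested_masks(self):
        s = make_slice(np.zeros((32, 32)))
        outer = iq.rasterize_polygon(square(2, 2, 28, 28), s)
        inner = iq.rasterize_polygon(square(8, 8, 20, 20), s)
        assert not (inner & ~outer).any()


def _ann(lumen, scm=None, adj=None, wall=None):
    return iq.AnnotationSet(
        patient_id="P01",
        slice_index=0,
        lumen_center=lumen,
        outer_wall=wall if wall is not None else square(lumen[0] - 1, lumen[1] - 1, lumen[0] + 1, lumen[1] + 1),
        scm=scm,
        adjacent_muscle=adj,
    )


class TestScmReference:
    def test_uniform_square_inside_roi(self):
        s = make_slice(np.full((60, 60), 50.0))
        ref = iq.scm_reference(s, _ann((30, 30), scm=square(24, 24, 36, 36)))
        assert ref.valid and ref.value == 50.0

    def test_scm_outside_roi_is_invalid_not_error(self):
        # SCM entirely > 2 cm from the lumen: no overlap with the 4 cm ROI,
        # so the slice is flagged for exclusion rather than raising.
        s = make_slice(np.full((60, 60), 50.0))
        ref = iq.scm_reference(s, _ann((5, 5), scm=square(40, 40, 50, 50)))
        assert not ref.valid
        assert not iq.scm_reference(s, _ann((30, 30), scm=None)).valid

    def test_half_inside_roi_uses_only_intersection(self):
        pixels = np.full((60, 60), 10.0)
        pixels[:, 30:] = 90.0
        s = make_slice(pixels)
        scm = square(20.5, 25.5, 40.5, 34.5)
        ann = _ann((10, 30), scm=scm)
        ref = iq.scm_reference(s, ann)
        inter = brute_polygon_mask(scm, s) & brute_circle_mask((10, 30), 40.0, s)
        assert ref.n_pixels == inter.sum()
        assert ref.value == pytest.approx(pixels[inter].mean(), abs=1e-12)
        assert pixels[inter].min() <= ref.value <= pixels[inter].max()


class TestAdjacentMuscleReference:
    def test_uniform(self):
        s = make_slice(np.full((20, 20), 80.0))
        ref = iq.adjacent_muscle_reference(s, _ann((10, 10), adj=square(2, 2, 8, 8)))
        assert ref.valid and ref.value == 80.0

    def test_three_pixel_mean(self):
        pixels = np.zeros((5, 5))
        pixels[2, 1:4] = [10.0, 20.0, 30.0]
        s = make_slice(pixels)
        ref = iq.adjacent_muscle_reference(s, _ann((2, 2), adj=square(0.6, 1.6, 3.4, 2.4)))
        assert ref.n_pixels == 3 and ref.value == 20.0

    def test_absent_polygon_invalid(self):
        s = make_slice(np.full((5, 5), 1.0))
        assert not iq.adjacent_muscle_reference(s, _ann((2, 2))).valid


class TestLocalMedianReference:
    def test_odd_and_even_counts(self):
        pixels = np.zeros((7, 7))
        # plus-shaped 5-pixel neighbourhood of (3, 3) at diameter 2
        pixels[3, 2:5] = [1.0, 3.0, 5.0]
        pixels[2, 3], pixels[4, 3] = 2.0, 4.0
        s = make_slice(pixels)
        ref = iq.local_median_reference(s, _ann((3.0, 3.0)), roi_diameter_mm=2.0)
        assert ref.n_pixels == 5 and ref.value == 3.0
        # two-pixel mask: midpoint convention
        pixels2 = np.zeros((7, 7))
        pixels2[2, 3], pixels2[3, 3] = 1.0, 4.0
        s2 = make_slice(pixels2)
        ref2 = iq.local_median_reference(s2, _ann((3.0, 2.5)), roi_diameter_mm=1.2)
        assert ref2.n_pixels == 2 and ref2.value == 2.5

    def test_random_image_matches_sorted_enumeration(self):
        rng = np.random.default_rng(5)
        s = make_slice(rng.uniform(0, 100, size=(64, 64)))
        ref = iq.local_median_reference(s, _ann((31, 31)), roi_diameter_mm=30.0)
        vals = np.sort(s.pixels[brute_circle_mask((31, 31), 30.0, s)])
        n = len(vals)
        expect = vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
        assert ref.value == expect

    def test_lumen_off_image_is_error(self):
        s = make_slice(np.full((10, 10), 1.0))
        ann = iq.AnnotationSet(
            patient_id="P01", slice_index=0, lumen_center=(500.0, 500.0),
            outer_wall=square(499, 499, 501, 501),
        )
        with pytest.raises(iq.ValidationError):
            iq.local_median_reference(s, ann, roi_diameter_mm=4.0)

    def test_median_ignores_pixels_outside_mask(self):
        rng = np.random.default_rng(6)
        s = make_slice(rng.uniform(0, 100, size=(40, 40)))
        ann = _ann((20, 20))
        ref = iq.local_median_reference(s, ann, roi_diameter_mm=10.0)
        outside = ~iq.rasterize_circle((20, 20), 10.0, s)
        perturbed = s.pixels.copy()
        perturbed[outside] = 9999.0
        ref2 = iq.local_median_reference(make_slice(perturbed), ann, roi_diameter_mm=10.0)
        assert ref2.value == ref.value


@settings(max_examples=25, deadline=None, derandomize=True)
@given(c=st.floats(min_value=0.01, max_value=1000.0, allow_nan=False))
def test_scale_equivariance_of_all_references(c):
    rng = np.random.default_rng(9)
    pixels = rng.uniform(1.0, 100.0, size=(48, 48))
    ann = iq.AnnotationSet(
        patient_id="P01", slice_index=0, lumen_center=(24.0, 24.0),
        outer_wall=square(20, 20, 28, 28), scm=square(10, 4, 38, 12),
        adjacent_muscle=square(32, 30, 40, 38),
    )
    for fn in (iq.scm_reference, iq.adjacent_muscle_reference, iq.local_median_reference):
        a = fn(make_slice(pixels), ann)
        b = fn(make_slice(pixels * c), ann)
        assert b.value == pytest.approx(c * a.value, rel=1e-12)
        assert b.n_pixels == a.n_pixels
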