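"""Contour I/O, areas, even-spacing resampling and cap thickness."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capmech.contours import (
    CapSamples,
    ContourValidationError,
    SliceContours,
    cap_thickness_profile,
    make_cap_samples,
    morphology,
    polygon_area,
    read_slice,
    resample_even,
    write_slice,
)

from _geometry import circle, octagon_square


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area([(0, 0), (1, 0), (1, 1), (0, 1)]) == pytest.approx(1.0)

    def test_triangle(self):
        assert polygon_area([(0, 0), (1, 0), (0, 1)]) == pytest.approx(0.5)

    def test_regular_ngon_closed_form(self):
        # area of a regular n-gon of circumradius R is n R^2 sin(2 pi/n) / 2
        n, R = 360, 2.0
        expected = 0.5 * n * R**2 * np.sin(2 * np.pi / n)
        assert polygon_area(circle(R, n)) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(np.pi * R**2, rel=1e-3)

    def test_circle_quadrature_within_0p1pct(self):
        assert polygon_area(circle(1.7, 360)) == pytest.approx(
            np.pi * 1.7**2, rel=1e-3
        )

    def test_orientation_independent(self):
        sq = octagon_square(2.0)
        assert polygon_area(sq) == pytest.approx(polygon_area(sq[::-1]))

    def test_too_few_vertices(self):
        with pytest.raises(ContourValidationError):
            polygon_area([(0, 0), (1, 0)])


class TestReadSlice:
    def _doc(self, lumen, outer, **kw):
        return {
            "slice_id": "s1",
            "patient_id": "p1",
            "timepoint": "baseline",
            "pressure_mmHg": {"dia": 70, "sys": 120},
            "contours": {"lumen": lumen, "outer": outer, **kw},
        }

    def test_nested_squares_valid(self, tmp_path):
        doc = self._doc(
            octagon_square(2.0, (1, 1)).tolist(), octagon_square(4.0, (1, 1)).tolist()
        )
        p = tmp_path / "s.json"
        p.write_text(json.dumps(doc))
        slc = read_slice(p)
        assert slc.slice_id == "s1"
        assert polygon_area(slc.lumen) == pytest.approx(4.0)

    def test_clockwise_lumen_normalized(self, tmp_path):
        doc = self._doc(
            octagon_square(2.0)[::-1].tolist(), octagon_square(4.0).tolist()
        )
        p = tmp_path / "s.json"
        p.write_text(json.dumps(doc))
        slc = read_slice(p)
        # counter-clockwise: positive signed area
        x, y = slc.lumen[:, 0], slc.lumen[:, 1]
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert signed > 0
        assert polygon_area(slc.lumen) == pytest.approx(4.0)

    def test_lumen_outside_outer_rejected(self, tmp_path):
        doc = self._doc(
            octagon_square(2.0, (3.5, 0)).tolist(), octagon_square(4.0).tolist()
        )
        p = tmp_path / "s.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ContourValidationError):
            read_slice(p)

    def test_self_intersecting_rejected(self, tmp_path):
        bow = [(0, 0), (2, 2), (2, 0), (0, 2), (-0.5, 1.8), (-1, 1.5), (-1, 0.7), (-0.5, 0.2)]
        doc = self._doc(bow, octagon_square(8.0).tolist())
        p = tmp_path / "s.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ContourValidationError):
            read_slice(p)

    def test_missing_field_named(self, tmp_path):
        p = tmp_path / "s.json"
        p.write_text(json.dumps({"slice_id": "x"}))
        with pytest.raises(ContourValidationError, match="patient_id"):
            read_slice(p)

    def test_round_trip(self, tmp_path, lipid_slice):
        p = tmp_path / "rt.json"
        write_slice(lipid_slice, p)
        back = read_slice(p)
        np.testing.assert_allclose(back.lumen, lipid_slice.lumen)
        assert len(back.lipids) == len(lipid_slice.lipids)


class TestMorphology:
    def test_plaque_burden_arithmetic(self):
        # LA = 4, outer area = 10 -> PA = 6, PB = 0.6
        slc = SliceContours(
            "s", "p", "baseline",
            octagon_square(2.0),
            octagon_square(np.sqrt(10.0)),
        )
        m = morphology(slc)
        assert m.LA == pytest.approx(4.0)
        assert m.PA == pytest.approx(6.0)
        assert m.PB == pytest.approx(0.6)

    def test_concentric_circles(self):
        slc = SliceContours("s", "p", "baseline", circle(1.5, 720), circle(3.0, 720))
        m = morphology(slc)
        assert m.LA == pytest.approx(np.pi * 1.5**2, rel=1e-3)
        assert m.PA == pytest.approx(np.pi * (3**2 - 1.5**2), rel=1e-3)
        assert m.PB == pytest.approx(0.75, rel=1e-3)

    def test_no_lipid_no_cap_stats(self, cylinder):
        m = morphology(cylinder)
        assert m.MinCapT is None and m.MeanCapT is None

    def test_pb_strictly_between_0_and_1(self, small_cohort):
        for pair in small_cohort:
            m = morphology(pair.baseline)
            assert 0.0 < m.PB < 1.0


class TestResampleEven:
    def test_square_spacing(self):
        pts = resample_even(octagon_square(1.0), 100)
        d = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        assert np.allclose(d, 0.04, atol=1e-12)

    def test_four_points_on_circle(self):
        pts = resample_even(circle(1.0, 3600), 4)
        ang = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
        steps = np.diff(np.unwrap(np.radians(ang)))
        assert np.allclose(np.degrees(steps), 90.0, atol=0.2)

    def test_perimeter_preserved(self, lipid_slice):
        pts = resample_even(lipid_slice.lumen, 100)
        orig = np.vstack([lipid_slice.lumen, lipid_slice.lumen[:1]])
        p_orig = np.sum(np.linalg.norm(np.diff(orig, axis=0), axis=1))
        p_new = np.sum(np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1))
        assert abs(p_new - p_orig) / p_orig < 0.005

    def test_densification_invariance(self):
        coarse = circle(1.3, 90)
        fine = circle(1.3, 900)
        a = resample_even(coarse, 50)
        b = resample_even(fine, 50)
        assert np.max(np.linalg.norm(a - b, axis=1)) < 5e-3

    def test_start_point_max_x(self):
        pts = resample_even(circle(2.0, 360), 100)
        assert pts[0, 0] == pytest.approx(2.0, abs=1e-6)
        assert pts[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_quarters_balanced(self, lipid_slice):
        s = make_cap_samples(lipid_slice)
        assert [np.sum(s.quarter == q) for q in (1, 2, 3, 4)] == [25, 25, 25, 25]

    def test_degenerate_rejected(self):
        with pytest.raises((ValueError, ContourValidationError)):
            resample_even([(0, 0)] * 10, 10)


class TestCapThickness:
    def test_annular_lipid_cap_thickness(self, annular_lipid_slice):
        samples = cap_thickness_profile(
            annular_lipid_slice, make_cap_samples(annular_lipid_slice)
        )
        min_t, mean_t = samples.cap_stats()
        assert min_t == pytest.approx(0.2, abs=0.01)
        # in-cap arc covers about a quarter of the lumen
        assert 15 <= int(np.sum(samples.in_cap)) <= 35
        assert min_t <= mean_t

    def test_cap_stats_track_category_thresholds(self, annular_lipid_slice):
        from capmech.pvi import DEFAULT_THRESHOLDS, score_pvi

        samples = cap_thickness_profile(
            annular_lipid_slice, make_cap_samples(annular_lipid_slice)
        )
        min_t, _ = samples.cap_stats()
        # a 0.2 mm cap sits in the thinnest (most vulnerable) category
        assert score_pvi(min_t, DEFAULT_THRESHOLDS["C"]) == 4

    def test_lipid_outside_cone_warns(self):
        lumen = circle(1.0, 120)
        outer = circle(3.0, 120)
        # lipid tucked fully behind the lumen centroid rays? impossible for a
        # star-shaped wall; emulate by a pool beyond the outer ring cone of
        # sample rays is not constructible, so check the no-in-cap warning by
        # a pool subtending a gap between consecutive rays
        th = np.linspace(0.001, 0.015, 30)  # < one sample-spacing arc
        inner = np.stack([1.4 * np.cos(th), 1.4 * np.sin(th)], axis=1)
        outer_arc = np.stack([1.6 * np.cos(th), 1.6 * np.sin(th)], axis=1)
        lipid = np.vstack([inner, outer_arc[::-1]])
        slc = SliceContours("s", "p", "baseline", lumen, outer, lipids=[lipid])
        samples = make_cap_samples(slc, n=8)
        with pytest.warns(UserWarning, match="cap statistics absent"):
            out = cap_thickness_profile(slc, samples)
        assert out.cap_stats() == (None, None)

    def test_rigid_motion_invariance(self, annular_lipid_slice):
        ref = cap_thickness_profile(
            annular_lipid_slice, make_cap_samples(annular_lipid_slice)
        ).cap_stats()
        moved = annular_lipid_slice.rotated(0.7).translated(3.3, -1.2)
        got = cap_thickness_profile(moved, make_cap_samples(moved)).cap_stats()
        assert got[0] == pytest.approx(ref[0], abs=1e-6)
        assert got[1] == pytest.approx(ref[1], abs=1e-3)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    pa=st.floats(0.5, 30.0),
    la=st.floats(0.5, 30.0),
    extra=st.floats(0.01, 10.0),
)
def test_pb_monotone_in_plaque_area(pa, la, extra):
    """PB = PA/(PA+LA) grows with PA at fixed LA."""
    pb1 = pa / (pa + la)
    pb2 = (pa + extra) / (pa + extra + la)
    assert 0 < pb1 < 1
    assert pb2 > pb1
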