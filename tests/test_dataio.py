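"""I/O round trips, polygon geometry and validation contracts."""

import json

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon as ShapelyPolygon

from mtpm import dataio
from mtpm.dataio import (AcquisitionMeta, CineEncodingSet, LVSegmentation,
                         RegionalTimeCourse, points_in_polygon,
                         polygon_area, rasterize_polygon, ccw_angle_deg)


def _meta(**kw):
    base = dict(fov_mm=25.6, matrix=16, frame_interval_ms=4.6, n_frames=3,
                venc_inplane_cm_s=6.0, venc_through_cm_s=8.0,
                slice_level="mid")
    base.update(kw)
    return AcquisitionMeta(**base)


class TestAcquisitionMeta:
    @pytest.mark.parametrize("field,value", [
        ("fov_mm", -1.0), ("matrix", 0), ("frame_interval_ms", 0.0),
        ("venc_inplane_cm_s", 0.0), ("venc_through_cm_s", -8.0),
        ("slice_level", "atrial"),
    ])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            _meta(**{field: value})

    def test_derived_quantities(self):
        m = _meta(fov_mm=25.6, matrix=16)
        assert m.voxel_mm == 1.6
        assert m.cycle_ms == pytest.approx(3 * 4.6)

    def test_missing_through_plane_venc_allowed(self):
        assert _meta(venc_through_cm_s=None).venc_through_cm_s is None


class TestCineEncodingSet:
    def test_identity_load(self):
        scans = np.zeros((4, 3, 16, 16), dtype=complex)
        cs = CineEncodingSet(scans=scans, meta=_meta(), domain="image")
        assert cs.meta.n_frames == 3
        assert cs.has_z
        assert cs.encodings == ("ref", "x", "y", "z")

    def test_frame_count_mismatch_is_error(self):
        scans = np.zeros((4, 5, 16, 16), dtype=complex)
        with pytest.raises(ValueError, match="encoding shape mismatch"):
            CineEncodingSet(scans=scans, meta=_meta(), domain="image")

    def test_z_encoding_requires_venc(self):
        scans = np.zeros((4, 3, 16, 16), dtype=complex)
        with pytest.raises(ValueError, match="venc"):
            CineEncodingSet(scans=scans, meta=_meta(venc_through_cm_s=None))

    def test_two_encoding_dataset_accepted(self):
        scans = np.zeros((3, 3, 16, 16), dtype=complex)
        cs = CineEncodingSet(scans=scans,
                             meta=_meta(venc_through_cm_s=None))
        assert not cs.has_z


class TestCineRoundTrip:
    @pytest.mark.parametrize("layout", ["per_encoding", "stacked"])
    def test_write_then_read_is_identity(self, tmp_path, layout):
        rng = np.random.default_rng(0)
        scans = rng.normal(size=(4, 3, 16, 16)) \
            + 1j * rng.normal(size=(4, 3, 16, 16))
        cs = CineEncodingSet(scans=scans, meta=_meta(), domain="kspace")
        dataio.write_cine_dataset(cs, tmp_path, layout=layout)
        back = dataio.read_cine_dataset(tmp_path)
        np.testing.assert_array_equal(back.scans, scans)
        assert back.meta == cs.meta
        assert back.domain == "kspace"

    def test_missing_venc_in_config_is_named(self, tmp_path):
        scans = np.zeros((4, 3, 16, 16), dtype=complex)
        cs = CineEncodingSet(scans=scans, meta=_meta(), domain="image")
        dataio.write_cine_dataset(cs, tmp_path)
        with pytest.raises(ValueError, match="venc_inplane"):
            dataio.read_cine_dataset(tmp_path, config={"venc_inplane": None})


def _star_polygon(rng, n_vertices=12, r_lo=2.0, r_hi=6.0, center=(8.0, 8.0)):
    th = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    r = rng.uniform(r_lo, r_hi, n_vertices)
    return np.column_stack([center[0] + r * np.cos(th),
                            center[1] + r * np.sin(th)])


class TestPolygonGeometry:
    def test_even_odd_rule_matches_shapely(self):
        # independent point-in-polygon oracle on random star polygons
        rng = np.random.default_rng(42)
        for _ in range(5):
            poly = _star_polygon(rng)
            sh = ShapelyPolygon(poly)
            pts = rng.uniform(0, 16, size=(400, 2))
            ours = points_in_polygon(pts, poly)
            theirs = np.array([sh.contains(Point(*p)) for p in pts])
            # boundary-grazing points may differ; none expected at random
            assert np.array_equal(ours, theirs)

    def test_shoelace_area_square(self):
        sq = [[0, 0], [2, 0], [2, 2], [0, 2]]
        assert polygon_area(sq) == pytest.approx(4.0)

    def test_open_polygon_rejected(self):
        with pytest.raises(ValueError, match="open polygon"):
            points_in_polygon(np.zeros((1, 2)), [[0, 0], [1, 1]])

    def test_ccw_angle_convention(self):
        # east -> 0, image-top (negative dy) -> 90, west -> 180
        assert ccw_angle_deg(1.0, 0.0) == pytest.approx(0.0)
        assert ccw_angle_deg(0.0, -1.0) == pytest.approx(90.0)
        assert ccw_angle_deg(-1.0, 0.0) == pytest.approx(180.0)


def _circle(c, r, n=128):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([c[0] + r * np.cos(th), c[1] + r * np.sin(th)])


class TestLVSegmentation:
    def test_concentric_circles_give_annulus(self):
        c = (12.8, 12.8)
        seg = LVSegmentation.from_contours([_circle(c, 4.0)],
                                           [_circle(c, 2.0)],
                                           matrix=128, voxel_mm=0.2)
        assert seg.masks.shape == (1, 128, 128)
        np.testing.assert_allclose(seg.centers_mm[0], c, atol=0.05)

    @pytest.mark.parametrize("matrix,tol", [(128, 0.02), (512, 0.005)])
    def test_mask_area_converges_to_analytic(self, matrix, tol):
        c = (12.8, 12.8)
        r_epi, r_endo = 4.0, 2.0
        seg = LVSegmentation.from_contours(
            [_circle(c, r_epi, 720)], [_circle(c, r_endo, 720)],
            matrix=matrix, voxel_mm=25.6 / matrix)
        area = seg.masks[0].sum() * (25.6 / matrix) ** 2
        analytic = np.pi * (r_epi ** 2 - r_endo ** 2)
        assert area == pytest.approx(analytic, rel=tol)

    def test_endo_outside_epi_is_error(self):
        c = (12.8, 12.8)
        with pytest.raises(ValueError, match="inside"):
            LVSegmentation.from_contours([_circle(c, 2.0)],
                                         [_circle(c, 4.0)],
                                         matrix=64, voxel_mm=0.4)

    def test_contour_json_roundtrip_and_regrid(self, tmp_path):
        c = (12.8, 12.8)
        seg = LVSegmentation.from_contours(
            [_circle(c, 4.0)], [_circle(c, 2.0)], matrix=64, voxel_mm=0.4,
            reference_polygon=[[20, 2], [24, 2], [24, 6], [20, 6]])
        dataio.write_contours(seg, tmp_path / "c.json")
        back = dataio.read_contours(tmp_path / "c.json")
        np.testing.assert_array_equal(back.masks, seg.masks)
        assert back.static_reference_mask.sum() \
            == seg.static_reference_mask.sum()
        hi = dataio.read_contours(tmp_path / "c.json", matrix=128)
        assert hi.masks.shape == (1, 128, 128)
        assert hi.voxel_mm == pytest.approx(0.2)


class TestRegionalTimeCourse:
    def test_series_length_must_match_times(self):
        with pytest.raises(ValueError, match="length"):
            RegionalTimeCourse(segment=1, compartment="full",
                               component="radial", values=np.zeros(5),
                               times_ms=np.zeros(4),
                               median_radius_mm=np.zeros(5))

    def test_segment_range_enforced(self):
        with pytest.raises(ValueError, match="segment"):
            RegionalTimeCourse(segment=17, compartment="full",
                               component="radial", values=np.zeros(4),
                               times_ms=np.zeros(4),
                               median_radius_mm=np.zeros(4))


class TestResults:
    def test_tables_and_manifest_roundtrip(self, tmp_path):
        df = pd.DataFrame({"segment": [1, 2], "value": [0.5, 0.6]})
        manifest = {"seed": 7, "config": {"venc_inplane": 6.0}}
        dataio.write_results({"peaks": df}, tmp_path, manifest)
        back = pd.read_csv(tmp_path / "peaks.csv")
        pd.testing.assert_frame_equal(back, df)
        assert dataio.read_manifest(tmp_path / "manifest.json") == manifest

    def test_empty_table_writes_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["segment", "value"])
        dataio.write_results({"empty": df}, tmp_path)
        text = (tmp_path / "empty.csv").read_text().strip()
        assert text == "segment,value"
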