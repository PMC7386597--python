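"""Cord geometry: helix construction, analytic metrics, meshing, export."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cordflow as cf
from cordflow.geometry import GeometryError, MeshingError


class TestCordSpec:
    def test_baseline_derived_quantities(self, baseline_spec):
        assert baseline_spec.helix_radius == pytest.approx(0.00645, abs=1e-12)
        assert baseline_spec.n_coils == pytest.approx(12.0)

    def test_unit_suffixed_input(self):
        spec = cf.CordSpec(cord_length="60 cm", uv_diameter="8.3 mm",
                           ua_diameter="4.2mm", coil_pitch="5 cm",
                           clearance="0.2 mm")
        base = cf.CordSpec()
        for name in ("cord_length", "uv_diameter", "ua_diameter",
                     "coil_pitch", "clearance"):
            assert getattr(spec, name) == pytest.approx(getattr(base, name))

    @pytest.mark.parametrize(
        "field,value",
        [
            ("cord_length", -1.0),
            ("uv_diameter", 0.0),
            ("coil_pitch", 0.7),      # exceeds cord length
            ("clearance", -1e-4),
            ("n_arteries", 3),
        ],
    )
    def test_invalid_spec_names_field(self, field, value):
        with pytest.raises(ValueError) as err:
            cf.CordSpec(**{field: value})
        assert field in str(err.value)

    def test_pitch_equal_to_length_gives_one_coil(self):
        spec = cf.CordSpec(coil_pitch=0.6)
        assert spec.n_coils == pytest.approx(1.0)


class TestBuildGeometry:
    def test_vein_is_straight_axial_line(self, baseline_geometry):
        uv = baseline_geometry.centerline("UV")
        assert np.allclose(uv.points[:, 1:], 0.0)
        assert uv.points[0, 0] == 0.0
        assert uv.points[-1, 0] == pytest.approx(0.6)

    def test_arteries_sit_on_helix_radius(self, baseline_geometry):
        for vid in ("UA1", "UA2"):
            ua = baseline_geometry.centerline(vid)
            radial = np.hypot(ua.points[:, 1], ua.points[:, 2])
            assert np.allclose(radial, 0.00645, rtol=1e-12)

    def test_arteries_separated_by_phase_offset(self, baseline_geometry):
        a = baseline_geometry.centerline("UA1").points
        b = baseline_geometry.centerline("UA2").points
        # same axial coordinates, transverse positions diametrically opposite
        assert np.allclose(a[:, 0], b[:, 0])
        assert np.allclose(a[:, 1:], -b[:, 1:], atol=1e-12)

    def test_points_per_coil_minimum_enforced(self, baseline_spec):
        with pytest.raises(ValueError):
            cf.build_cord_geometry(baseline_spec, points_per_coil=4)

    def test_single_artery_option(self):
        geom = cf.build_cord_geometry(cf.CordSpec(n_arteries=1))
        assert set(geom.centerlines) == {"UV", "UA1"}


class TestArcLength:
    def test_straight_vein_length(self, baseline_geometry):
        assert cf.arc_length(baseline_geometry.centerline("UV")) == (
            pytest.approx(0.6)
        )

    def test_helix_matches_closed_form(self, baseline_spec):
        geom = cf.build_cord_geometry(baseline_spec, points_per_coil=512)
        closed = cf.helix_arc_length(12, 0.00645, 0.05)
        assert cf.arc_length(geom.centerline("UA1")) == (
            pytest.approx(closed, rel=1e-5)
        )

    def test_polyline_integration_oracle(self, baseline_spec):
        """High-resolution trapezoidal integration of |dr/dtheta| agrees with
        both the closed form and the polyline sum."""
        r_h, pitch, n = 0.00645, 0.05, 12.0
        theta = np.linspace(0, 2 * np.pi * n, 200_001)
        speed = np.hypot(r_h, pitch / (2 * np.pi))  # |dr/dtheta| is constant
        oracle = np.trapezoid(np.full_like(theta, speed), theta)
        assert oracle == pytest.approx(cf.helix_arc_length(n, r_h, pitch),
                                       rel=1e-12)

    def test_degenerate_helix_radius_collapses_to_cord_length(self):
        geom = cf.build_cord_geometry(cf.CordSpec(), helix_radius=0.0)
        assert cf.arc_length(geom.centerline("UA1")) == pytest.approx(0.6)

    def test_ua_arc_exceeds_cord_length(self, baseline_geometry):
        assert baseline_geometry.arc_lengths["UA1"] > 0.6


class TestWallArea:
    def test_straight_length_convention_matches_flux_denominators(
        self, baseline_geometry
    ):
        assert cf.wall_area(baseline_geometry, "UV") == (
            pytest.approx(0.0156, rel=1e-2)
        )
        assert cf.wall_area(baseline_geometry, "UA1") == (
            pytest.approx(0.00791, rel=1e-2)
        )

    def test_arc_length_convention_is_larger_for_arteries(self, baseline_geometry):
        a_arc = cf.wall_area(baseline_geometry, "UA1", convention="arc_length")
        a_straight = cf.wall_area(baseline_geometry, "UA1")
        assert a_arc / a_straight == pytest.approx(
            baseline_geometry.arc_lengths["UA1"] / 0.6
        )

    def test_maternal_vessel_area(self):
        # 8.3 mm diameter over the 0.04 m placental thickness
        assert cf.lateral_tube_area(0.0083, 0.04) == pytest.approx(0.00103,
                                                                   rel=2e-2)

    def test_unknown_vessel_rejected(self, baseline_geometry):
        with pytest.raises(KeyError):
            cf.wall_area(baseline_geometry, "MV")


class TestUCI:
    def test_baseline_uci(self, baseline_geometry):
        assert baseline_geometry.uci == pytest.approx(0.2)

    def test_single_turn_short_cord_same_uci(self):
        geom = cf.build_cord_geometry(cf.CordSpec(cord_length=0.05,
                                                  coil_pitch=0.05))
        assert geom.uci == pytest.approx(0.2)

    def test_doubling_pitch_halves_uci(self):
        half = cf.build_cord_geometry(cf.CordSpec(coil_pitch=0.1))
        assert half.uci == pytest.approx(0.1)

    @pytest.mark.parametrize("ppc", [16, 32, 64, 128])
    def test_resolution_invariant(self, baseline_spec, ppc):
        geom = cf.build_cord_geometry(baseline_spec, points_per_coil=ppc)
        assert cf.compute_uci(geom) == pytest.approx(0.2, abs=1e-9)


class TestClearance:
    def test_baseline_gap_equals_spec_clearance(self, baseline_geometry):
        gaps = cf.check_clearance(baseline_geometry)
        assert gaps["UV-UA1"] == pytest.approx(2e-4, abs=1e-12)
        assert gaps["UV-UA2"] == pytest.approx(2e-4, abs=1e-12)

    def test_arteries_never_touch(self, baseline_geometry):
        gaps = cf.check_clearance(baseline_geometry)
        assert gaps["UA1-UA2"] > 0

    def test_zero_clearance_tangent_tubes(self):
        geom = cf.build_cord_geometry(cf.CordSpec(clearance=0.0))
        gaps = cf.check_clearance(geom)
        assert gaps["UV-UA1"] == pytest.approx(0.0, abs=1e-12)

    def test_forced_interpenetration_raises(self, baseline_spec):
        geom = cf.build_cord_geometry(baseline_spec, helix_radius=0.005)
        with pytest.raises(GeometryError):
            cf.check_clearance(geom)


class TestSweepMesh:
    def test_straight_tube_area_within_1pct_at_64_segments(self):
        cl = cf.geometry.build_straight_centerline("UV", 0.6, 0.00415)
        mesh = cf.sweep_tube_mesh(cl, 64, cap_ends=False)
        analytic = math.pi * 0.0083 * 0.6
        assert mesh.surface_area() == pytest.approx(analytic, rel=0.01)

    def test_area_error_decreases_monotonically(self, baseline_geometry):
        cl = baseline_geometry.centerline("UA1")
        analytic = math.pi * 0.0042 * baseline_geometry.arc_lengths["UA1"]
        errors = []
        for segs in (8, 16, 32, 64):
            mesh = cf.sweep_tube_mesh(cl, segs, cap_ends=False)
            errors.append(abs(mesh.surface_area() - analytic))
        assert errors == sorted(errors, reverse=True)

    def test_capped_tube_is_watertight(self, baseline_geometry):
        mesh = cf.sweep_tube_mesh(baseline_geometry.centerline("UA1"), 16,
                                  cap_ends=True)
        assert mesh.is_watertight()
        # independent cross-check with trimesh's watertightness
        import trimesh

        tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
        assert tm.is_watertight

    def test_no_degenerate_triangles(self, baseline_geometry):
        mesh = cf.sweep_tube_mesh(baseline_geometry.centerline("UA1"), 16)
        v, t = mesh.vertices, mesh.triangles
        areas = 0.5 * np.linalg.norm(
            np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]), axis=1
        )
        assert np.all(areas > 0)

    def test_baseline_artery_sweep_within_curvature_bound(self, baseline_geometry):
        # helix curvature radius ~16 mm >> tube radius 2.1 mm: must not raise
        cf.sweep_tube_mesh(baseline_geometry.centerline("UA1"), 8)

    def test_self_intersecting_sweep_rejected(self, baseline_spec):
        # a fat tube on a tight helix: curvature radius < tube radius
        spec = cf.CordSpec(cord_length=0.05, coil_pitch=0.01,
                           ua_diameter=0.02, uv_diameter=0.002,
                           clearance=0.0)
        geom = cf.build_cord_geometry(spec, helix_radius=0.003)
        with pytest.raises(MeshingError):
            cf.sweep_tube_mesh(geom.centerline("UA1"), 8)

    def test_too_few_segments_rejected(self, baseline_geometry):
        with pytest.raises(ValueError):
            cf.sweep_tube_mesh(baseline_geometry.centerline("UV"), 2)


@pytest.fixture(scope="module")
def mesh(baseline_geometry):
    return cf.sweep_tube_mesh(baseline_geometry.centerline("UA1"), 16)


class TestMeshExport:

    def test_stl_round_trip_preserves_triangles(self, mesh, tmp_path):
        path = tmp_path / "ua.stl"
        cf.export_mesh(mesh, path)
        back = cf.read_mesh(path)
        assert back.n_triangles == mesh.n_triangles

    def test_vtk_round_trip_preserves_vertices(self, mesh, tmp_path):
        path = tmp_path / "ua.vtk"
        cf.export_mesh(mesh, path)
        back = cf.read_mesh(path)
        assert back.n_vertices == mesh.n_vertices
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)
        assert np.array_equal(back.triangles, mesh.triangles)

    def test_empty_mesh_rejected(self, tmp_path):
        empty = cf.TubeSurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), int),
                                   "UV", False)
        with pytest.raises(ValueError):
            cf.export_mesh(empty, tmp_path / "x.stl")

    def test_centerline_csv_export(self, baseline_geometry, tmp_path):
        import pandas as pd

        path = tmp_path / "uv.csv"
        cf.export_centerline_csv(baseline_geometry.centerline("UV"), path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["x_m", "y_m", "z_m", "arclength_m"]
        assert len(df) == len(baseline_geometry.centerline("UV").points)


class TestProperties:
    @given(
        d_uv=st.floats(0.004, 0.02),
        d_ua=st.floats(0.002, 0.01),
        clearance=st.floats(0.0, 0.002),
    )
    def test_helix_radius_composition(self, d_uv, d_ua, clearance):
        spec = cf.CordSpec(uv_diameter=d_uv, ua_diameter=d_ua,
                           clearance=clearance)
        assert spec.helix_radius == d_uv / 2 + d_ua / 2 + clearance

    @given(pitch=st.floats(0.02, 0.3))
    def test_uci_tracks_inverse_pitch(self, pitch):
        spec = cf.CordSpec(cord_length=0.6, coil_pitch=pitch)
        geom = cf.build_cord_geometry(spec, points_per_coil=16)
        assert cf.compute_uci(geom) == pytest.approx(1.0 / (100.0 * pitch),
                                                     rel=1e-9)

    def test_ua_arc_converges_to_cord_length_as_radius_vanishes(self):
        spec = cf.CordSpec()
        lengths = [
            cf.arc_length(
                cf.build_cord_geometry(spec, helix_radius=r).centerline("UA1")
            )
            for r in (0.00645, 0.003, 0.001, 1e-4)
        ]
        assert all(l > 0.6 for l in lengths[:-1])
        assert lengths == sorted(lengths, reverse=True)
        assert lengths[-1] == pytest.approx(0.6, rel=1e-4)
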