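"""Mesh primitives: lofting, revolution, volume and metrology."""

import numpy as np
import pytest
import trimesh as tm
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiosynth import (
    EllipseSection,
    TriMesh,
    is_watertight,
    loft_ellipses,
    mesh_metrics,
    mesh_volume,
    polygon_correction,
    revolve_with_bulge,
)
from cardiosynth.geometry import points_to_surface_distance

from conftest import random_rotation


def circular_sections(radii, z):
    return [EllipseSection(z=zi, ax=r, ay=r) for zi, r in zip(z, radii)]


def frustum_stack_volume(radii, z):
    """Analytic volume of the solid of revolution with piecewise-linear radius."""
    radii = np.asarray(radii, dtype=float)
    z = np.asarray(z, dtype=float)
    r1, r2 = radii[:-1], radii[1:]
    return float(np.pi / 3.0 * np.sum(np.diff(z) * (r1**2 + r1 * r2 + r2**2)))


class TestLoft:
    def test_prism_volume_matches_polygon_closed_form(self):
        # two circular sections r=30 at z=0, 80: an n-gonal prism
        mesh = loft_ellipses(circular_sections([30, 30], [0, 80]), n_theta=256)
        expected = 256 / 2 * np.sin(2 * np.pi / 256) * 30**2 * 80  # ~226171.96 mm^3
        assert mesh_volume(mesh) == pytest.approx(expected, rel=1e-12)

    def test_cone_volume_converges_to_analytic(self):
        # linear taper 30 -> ~0 over 80 mm: (1/3) pi r^2 h = 75398.2 mm^3
        mesh = loft_ellipses(circular_sections([30, 0.03], [0, 80]), n_theta=256)
        assert mesh_volume(mesh) == pytest.approx(np.pi / 3 * 30**2 * 80, rel=5e-3)

    def test_capped_loft_is_watertight(self):
        mesh = loft_ellipses(circular_sections([11, 25, 14], [0, 40, 80]), n_theta=32)
        assert is_watertight(mesh)
        open_mesh = loft_ellipses(circular_sections([11, 25], [0, 40]), n_theta=32, cap_ends=False)
        assert not is_watertight(open_mesh)

    def test_rejects_degenerate_requests(self):
        with pytest.raises(ValueError, match="at least 2 sections"):
            loft_ellipses(circular_sections([30], [0]))
        with pytest.raises(ValueError, match="strictly ordered"):
            loft_ellipses(circular_sections([30, 20, 25], [0, 50, 40]))
        with pytest.raises(ValueError, match="n_theta"):
            loft_ellipses(circular_sections([30, 30], [0, 80]), n_theta=4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        radii=st.lists(st.floats(5.0, 40.0), min_size=2, max_size=6),
        n_theta=st.sampled_from([16, 64, 128]),
    )
    def test_volume_matches_frustum_oracle_for_random_profiles(self, radii, n_theta):
        # discrete loft volume = analytic solid-of-revolution integral times
        # the inscribed-polygon correction, to machine precision
        z = np.linspace(0.0, 10.0 * len(radii), len(radii))
        mesh = loft_ellipses(circular_sections(radii, z), n_theta=n_theta)
        expected = polygon_correction(n_theta) * frustum_stack_volume(radii, z)
        assert mesh_volume(mesh) == pytest.approx(expected, rel=1e-10)


class TestRevolve:
    def test_zero_bulge_equals_plain_revolve(self):
        profile = [(10.0, 0.0), (10.0, 5.0), (10.0, 20.0)]
        plain = revolve_with_bulge(profile, n_theta=64)
        bulged = revolve_with_bulge(profile, n_theta=64, bulge=lambda z, th: np.zeros_like(th))
        np.testing.assert_array_equal(plain.vertices, bulged.vertices)

    def test_max_radius_is_profile_plus_bulge_peak(self):
        d = 2.5
        profile = [(10.0, float(z)) for z in range(0, 21, 2)]
        mesh = revolve_with_bulge(profile, n_theta=96, bulge=lambda z, th: d * np.maximum(0, np.cos(3 * th)))
        r = np.hypot(mesh.vertices[:, 0], mesh.vertices[:, 1])
        assert r.max() == pytest.approx(10.0 + d, abs=1e-12)

    def test_threefold_bulge_gives_three_disjoint_sectors(self):
        # max(0, cos 3theta) is positive on exactly 3 disjoint arcs of [0, 2pi)
        profile = [(10.0, 0.0), (10.0, 10.0)]
        mesh = revolve_with_bulge(profile, n_theta=360, bulge=lambda z, th: 2.0 * np.maximum(0, np.cos(3 * th)))
        ring = mesh.vertices[:360]
        bulged = np.hypot(ring[:, 0], ring[:, 1]) > 10.0 + 1e-9
        n_runs = int(np.sum(np.diff(bulged.astype(int)) == 1) + (bulged[0] and not bulged[-1]))
        assert n_runs == 3

    def test_rejects_negative_radius(self):
        with pytest.raises(ValueError, match="non-positive radius|non-negative"):
            revolve_with_bulge([(1.0, 0.0), (1.0, 1.0)], bulge=lambda z, th: -2.0 * np.ones_like(th))


class TestMeshVolume:
    def test_unit_cube(self, unit_cube):
        assert unit_cube.n_faces == 12
        assert mesh_volume(unit_cube) == pytest.approx(1.0, rel=1e-12)

    def test_icosphere_volume(self):
        ico = tm.creation.icosphere(subdivisions=4, radius=10.0)
        mesh = TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        assert mesh_volume(mesh) == pytest.approx(4.0 / 3.0 * np.pi * 1000.0, rel=5e-3)
        # independent cross-check against trimesh's own divergence-theorem volume
        assert mesh_volume(mesh) == pytest.approx(ico.volume, rel=1e-12)

    def test_open_mesh_rejected(self, unit_cube):
        opened = TriMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(ValueError, match="watertight"):
            mesh_volume(opened)

    def test_invariant_under_rigid_motion_and_face_permutation(self, unit_cube):
        v0 = mesh_volume(unit_cube)
        moved = unit_cube.transformed(rotation=random_rotation(3), translation=(4.0, -7.0, 11.0))
        assert mesh_volume(moved) == pytest.approx(v0, rel=1e-12)
        perm = np.random.default_rng(0).permutation(unit_cube.n_faces)
        assert mesh_volume(TriMesh(unit_cube.vertices, unit_cube.faces[perm])) == pytest.approx(v0, rel=1e-12)


class TestMeshMetrics:
    def test_cylinder(self):
        mesh = loft_ellipses(circular_sections([30, 30], [0, 80]), n_theta=64)
        m = mesh_metrics(mesh)
        assert m.height == pytest.approx(80.0)
        assert m.radius_min == pytest.approx(30.0)
        assert m.radius_max == pytest.approx(30.0)
        assert m.radius_avg == pytest.approx(30.0)

    def test_cone_apex_band_excluded(self):
        # apex-exclusion keeps the vanishing tip out of the radius statistics
        radii = np.linspace(30.0, 0.05, 41)
        mesh = loft_ellipses(circular_sections(radii, np.linspace(0, 80, 41)), n_theta=64)
        m = mesh_metrics(mesh)
        assert m.radius_max == pytest.approx(30.0)
        assert m.radius_min > 0.05

    def test_zero_axis_rejected(self, unit_cube):
        with pytest.raises(ValueError, match="axis"):
            mesh_metrics(unit_cube, axis=(0, 0, 0))


class TestPointSurfaceDistance:
    def test_concentric_spheres(self):
        inner = tm.creation.icosphere(subdivisions=3, radius=20.0)
        outer = tm.creation.icosphere(subdivisions=3, radius=25.0)
        target = TriMesh(np.asarray(outer.vertices), np.asarray(outer.faces))
        d = points_to_surface_distance(np.asarray(inner.vertices), target)
        assert d.min() == pytest.approx(5.0, abs=0.05)
        assert d.max() == pytest.approx(5.0, abs=0.05)
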