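"""Tests for target construction, phantoms and the COG/COV/COS reference points."""

import numpy as np
import pytest
import trimesh

import isomargin as im
from isomargin.geometry import PHANTOM_CONFIGS


class TestSphereTarget:
    def test_analytic_volume_and_area(self):
        t = im.make_sphere_target((0, 0, 0), 10.0)
        assert t.volume == pytest.approx(np.pi / 6 * 1000, rel=1e-9)
        assert t.surface_area == pytest.approx(np.pi * 100, rel=1e-9)

    def test_samples_on_sphere_and_centered(self):
        center = np.array([5.0, -2.0, 13.0])
        t = im.make_sphere_target(center, 12.0)
        r = np.linalg.norm(t.points - center, axis=1)
        assert np.all(np.abs(r - 6.0) < 1e-6)
        assert np.linalg.norm(t.points.mean(axis=0) - center) < 0.01

    def test_density_request_honoured(self):
        t = im.make_sphere_target((0, 0, 0), 20.0, points_per_mm2=2.0)
        assert t.points.shape[0] >= 2.0 * t.surface_area

    def test_invalid_diameter(self):
        with pytest.raises(ValueError):
            im.make_sphere_target((0, 0, 0), 0.0)


class TestPhantoms:
    def test_two_sphere_separation(self):
        ts = im.make_phantom("two-5-10")
        assert np.linalg.norm(ts.targets[0].centroid - ts.targets[1].centroid) == pytest.approx(100.0)

    def test_three_sphere_centers(self):
        ts = im.make_phantom("three-5-10-20")
        np.testing.assert_allclose(
            ts.centroids, [[100, 0, 0], [0, 100, 0], [0, 0, 100]], atol=1e-12
        )

    def test_six_sphere_diameters(self):
        ts = im.make_phantom("six")
        diams = sorted(t.sphere_params[1] for t in ts.targets)
        assert diams == [4, 8, 10, 12, 16, 18]

    def test_unknown_config(self):
        with pytest.raises(KeyError):
            im.make_phantom("two-7-13")

    def test_all_documented_configs_build(self):
        for cid in PHANTOM_CONFIGS:
            assert im.make_phantom(cid, points_per_mm2=0.2).n >= 1


class TestReferenceIsocenters:
    def test_cog_midpoint(self):
        ts = im.two_sphere_phantom(8.0, 8.0)
        np.testing.assert_allclose(im.center_of_geometry(ts), [50, 0, 0], atol=1e-12)

    def test_cov_volume_weights(self):
        ts = im.two_sphere_phantom(5.0, 10.0)
        # weights proportional to D^3: x = 100 * 1000 / 1125
        assert im.center_of_volume(ts)[0] == pytest.approx(100 * 1000 / 1125, rel=1e-9)

    def test_cos_area_weights(self):
        ts = im.two_sphere_phantom(5.0, 10.0)
        # weights proportional to D^2: x = 100 * 100 / 125
        assert im.center_of_surface(ts)[0] == pytest.approx(80.0, rel=1e-9)

    def test_single_target_everything_is_centroid(self):
        ts = im.TargetSet((im.make_sphere_target((3, 4, 5), 7.0),))
        for f in (im.center_of_geometry, im.center_of_volume, im.center_of_surface):
            np.testing.assert_allclose(f(ts), [3, 4, 5], atol=1e-9)

    def test_congruent_spheres_coincide(self):
        ts = im.three_sphere_phantom((10, 10, 10))
        cog = im.center_of_geometry(ts)
        assert np.linalg.norm(im.center_of_volume(ts) - cog) < 0.01
        assert np.linalg.norm(im.center_of_surface(ts) - cog) < 0.01

    def test_cos_between_cog_and_cov(self):
        ts = im.two_sphere_phantom(5.0, 10.0)
        x_cog = im.center_of_geometry(ts)[0]
        x_cos = im.center_of_surface(ts)[0]
        x_cov = im.center_of_volume(ts)[0]
        assert x_cog < x_cos < x_cov

    def test_reference_points_inside_centroid_hull(self):
        ts = im.three_sphere_phantom((5, 10, 20))
        lo, hi = ts.centroid_bounds()
        for f in (im.center_of_geometry, im.center_of_volume, im.center_of_surface):
            p = f(ts)
            assert np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9)

    def test_rigid_equivariance(self):
        rng = np.random.default_rng(7)
        rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        shift = np.array([4.0, -11.0, 2.5])
        diams = (5.0, 10.0, 20.0)
        ts = im.three_sphere_phantom(diams, points_per_mm2=0.5)
        moved = im.TargetSet(
            tuple(
                im.make_sphere_target(rot @ c + shift, d, label=f"T{i}", points_per_mm2=0.5)
                for i, (c, d) in enumerate(zip(ts.centroids, diams))
            )
        )
        for f in (im.center_of_geometry, im.center_of_volume, im.center_of_surface):
            np.testing.assert_allclose(f(moved), rot @ f(ts) + shift, atol=1e-9)

    def test_cos_insensitive_to_sampling_density(self):
        a = im.center_of_surface(im.two_sphere_phantom(5, 10, points_per_mm2=1.0))
        b = im.center_of_surface(im.two_sphere_phantom(5, 10, points_per_mm2=2.0))
        assert np.linalg.norm(a - b) < 0.1


class TestMeshTargets:
    def test_unit_cube_properties(self):
        vol, area, centroid = im.mesh_properties(trimesh.creation.box(extents=(1, 1, 1)))
        assert vol == pytest.approx(1.0, rel=1e-9)
        assert area == pytest.approx(6.0, rel=1e-9)
        np.testing.assert_allclose(centroid, 0.0, atol=1e-9)

    def test_icosphere_volume_near_closed_form(self):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
        vol, area, _ = im.mesh_properties(mesh)
        assert vol == pytest.approx(np.pi / 6 * 1000, rel=5e-3)
        assert area == pytest.approx(np.pi * 100, rel=5e-3)

    def test_flipped_orientation_detected(self):
        mesh = trimesh.creation.box(extents=(1, 1, 1))
        mesh.invert()
        with pytest.raises(ValueError, match="volume"):
            im.mesh_properties(mesh)

    def test_open_mesh_rejected(self):
        mesh = trimesh.creation.box(extents=(1, 1, 1))
        open_mesh = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces[:-2])
        with pytest.raises(ValueError):
            im.mesh_properties(open_mesh)

    def test_mesh_target_round_numbers(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        t = im.make_mesh_target(mesh, label="m")
        assert t.source == "mesh"
        assert t.volume == pytest.approx(np.pi / 6 * 1000, rel=2e-2)

    def test_point_cloud_uses_convex_hull(self, caplog):
        pts = im.make_sphere_target((0, 0, 0), 10.0, points_per_mm2=0.5).points
        with caplog.at_level("WARNING"):
            t = im.make_point_cloud_target(pts, label="pc")
        assert t.source == "point_cloud"
        assert t.volume == pytest.approx(np.pi / 6 * 1000, rel=5e-2)
        assert any("convex hull" in r.message for r in caplog.records)


class TestTargetSetValidation:
    def test_duplicate_labels_rejected(self):
        t = im.make_sphere_target((0, 0, 0), 5.0, label="a")
        with pytest.raises(ValueError):
            im.TargetSet((t, t))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            im.TargetSet(())

    def test_totals(self):
        ts = im.two_sphere_phantom(5.0, 10.0)
        assert ts.total_volume == pytest.approx(np.pi / 6 * (125 + 1000), rel=1e-9)
        assert ts.total_surface_area == pytest.approx(np.pi * (25 + 100), rel=1e-9)
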