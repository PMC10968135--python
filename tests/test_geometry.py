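"""Mesh geometry: volumes, clipping, diameters, surface I/O."""

import numpy as np
import pytest
import trimesh
from hypothesis import given
from hypothesis import strategies as st

from aortagrowth.geometry import (CAP_FIELD, Centerline, Plane, TriSurface,
                                  clip_by_plane, enclosed_volume,
                                  max_diameter, read_surface, write_surface)
from aortagrowth.vtkio import VtkParseError

from _oracles import column_volume


def _tetrahedron():
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriSurface(v, f).oriented()


class TestEnclosedVolume:
    def test_unit_cube(self, unit_cube):
        assert enclosed_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)

    def test_tetrahedron_analytic(self):
        assert enclosed_volume(_tetrahedron()) == pytest.approx(1 / 6, rel=1e-12)

    def test_icosphere_discretization_deficit(self):
        # vertices on the sphere: the inscribed mesh underestimates the
        # analytic volume by the level-4 subdivision deficit (~0.216 %)
        sp = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
        v = enclosed_volume(TriSurface(sp.vertices, sp.faces))
        analytic = 4.0 / 3.0 * np.pi * 1000.0
        assert v < analytic
        assert abs(v - analytic) / analytic < 2.2e-3

    def test_icosphere_refinement_converges_monotonically(self):
        analytic = 4.0 / 3.0 * np.pi * 1000.0
        errs = []
        areas = []
        for sub in (2, 3, 4):
            sp = trimesh.creation.icosphere(subdivisions=sub, radius=10.0)
            m = TriSurface(sp.vertices, sp.faces)
            errs.append(analytic - enclosed_volume(m))
            areas.append(4.0 * np.pi * 100.0 - m.total_area)
        assert errs[0] > errs[1] > errs[2] > 0
        assert areas[0] > areas[1] > areas[2] > 0

    def test_open_mesh_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        open_mesh = TriSurface(v, np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="cap"):
            enclosed_volume(open_mesh)

    def test_rigid_invariance(self, unit_cube, rng):
        from aortagrowth.synthetic import random_rigid_transform
        v0 = enclosed_volume(unit_cube)
        for _ in range(20):
            t = random_rigid_transform(rng, max_translation_mm=50.0)
            moved = unit_cube.transformed(t.rotation, t.translation)
            assert enclosed_volume(moved) == pytest.approx(v0, rel=1e-9)

    def test_column_sampling_oracle(self):
        sp = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        m = TriSurface(sp.vertices, sp.faces)
        pitch = 0.1
        oracle = column_volume(m.vertices, m.faces, pitch=pitch)
        assert abs(oracle - enclosed_volume(m)) < m.total_area * pitch


class TestClipByPlane:
    def test_half_cube(self, unit_cube):
        half = clip_by_plane(unit_cube, Plane([0, 0, 0], [0, 0, 1]), "negative")
        assert half.is_closed
        assert enclosed_volume(half) == pytest.approx(0.5, rel=1e-12)

    def test_plane_missing_mesh_is_identity(self, unit_cube):
        same = clip_by_plane(unit_cube, Plane([0, 0, 5], [0, 0, 1]), "negative")
        assert enclosed_volume(same) == pytest.approx(1.0, rel=1e-12)

    def test_entire_mesh_removed_raises(self, unit_cube):
        with pytest.raises(ValueError, match="entire"):
            clip_by_plane(unit_cube, Plane([0, 0, 5], [0, 0, 1]), "positive")

    def test_cylinder_mid_height(self):
        cyl = trimesh.creation.cylinder(radius=5.0, height=20.0, sections=128)
        m = TriSurface(cyl.vertices, cyl.faces).oriented()
        lower = clip_by_plane(m, Plane([0, 0, 0], [0, 0, 1]), "negative")
        # inscribed 128-gon cross-section: known facet deficit sinc(2 pi/n)
        n = 128
        expect = np.pi * 25.0 * 10.0 * (n / (2 * np.pi)) * np.sin(2 * np.pi / n)
        assert enclosed_volume(lower) == pytest.approx(expect, rel=1e-6)

    def test_volume_additivity(self, unit_cube, rng):
        for _ in range(15):
            normal = rng.normal(size=3)
            plane = Plane(rng.uniform(-0.4, 0.4, 3), normal)
            pos = clip_by_plane(unit_cube, plane, "positive")
            neg = clip_by_plane(unit_cube, plane, "negative")
            total = enclosed_volume(pos) + enclosed_volume(neg)
            assert total == pytest.approx(1.0, rel=1e-8)

    def test_field_inheritance_and_cap_flag(self, unit_cube):
        field = np.arange(unit_cube.n_faces, dtype=float) + 10.0
        tagged = TriSurface(unit_cube.vertices, unit_cube.faces,
                            {"pressure": field})
        half = clip_by_plane(tagged, Plane([0, 0, 0.25], [0, 0, 1]), "negative")
        cap = half.cap_mask()
        assert cap.sum() > 0
        # children carry a parent value; caps carry 0
        child_vals = half.face_fields["pressure"][~cap]
        assert set(np.round(child_vals, 9)).issubset(set(field))
        assert np.all(half.face_fields["pressure"][cap] == 0.0)
        # second clip keeps the first clip's caps flagged
        again = clip_by_plane(half, Plane([0.2, 0, 0], [1, 0, 0]), "negative")
        assert again.face_fields[CAP_FIELD].sum() > 0


class TestMaxDiameter:
    def test_straight_cylinder_constant(self):
        cyl = trimesh.creation.cylinder(radius=25.0, height=40.0, sections=128)
        m = TriSurface(cyl.vertices, cyl.faces).oriented()
        axis = Centerline([[0, 0, -20.0], [0, 0, 20.0]])
        d, _ = max_diameter(m, axis, n_stations=6)
        assert d == pytest.approx(50.0, rel=2e-3)

    def test_bulged_aorta_equivalent_diameter(self, test_aorta,
                                              test_aorta_params):
        d, s = max_diameter(test_aorta.surface, test_aorta.centerline,
                            n_stations=60)
        p = test_aorta_params
        expect = p.annulus_diameter_mm * (1.0 + p.bulge_amplitude)
        assert d == pytest.approx(expect, rel=1e-2)
        bulge_s = p.s_annulus + p.bulge_center_frac * p.ascending_length_mm
        assert abs(s - bulge_s) < 5.0

    def test_two_stations_on_tapered_tube(self):
        # frustum from r=10 at z=0 to r=5 at z=20
        n = 64
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        ring0 = np.c_[10 * np.cos(theta), 10 * np.sin(theta), np.zeros(n)]
        ring1 = np.c_[5 * np.cos(theta), 5 * np.sin(theta), np.full(n, 20.0)]
        verts = np.vstack([ring0, ring1, [[0, 0, 0]], [[0, 0, 20.0]]])
        faces = []
        for j in range(n):
            k = (j + 1) % n
            faces += [(j, n + j, n + k), (j, n + k, k),
                      (2 * n, j, k), (2 * n + 1, n + k, n + j)]
        m = TriSurface(verts, np.asarray(faces)).oriented()
        d, _ = max_diameter(m, Centerline([[0, 0, 0], [0, 0, 20.0]]),
                            n_stations=2)
        assert d == pytest.approx(20.0, rel=1e-2)

    def test_all_stations_failing_raises(self, unit_cube):
        away = Centerline([[5, 5, 5], [6, 6, 6]])
        with pytest.raises(ValueError, match="no station"):
            with pytest.warns(UserWarning):
                max_diameter(unit_cube, away, n_stations=3)


class TestSurfaceIO:
    def test_stl_roundtrip_ascii_and_binary(self, unit_cube, tmp_path):
        for binary in (False, True):
            path = tmp_path / f"cube_{binary}.stl"
            write_surface(unit_cube, path, binary=binary)
            back = read_surface(path)
            assert len(back.vertices) == 8
            assert back.n_faces == 12
            assert enclosed_volume(back.oriented()) == pytest.approx(1.0)

    def test_vtk_roundtrip_preserves_fields_bitwise(self, unit_cube, tmp_path,
                                                    rng):
        fields = {"pressure": rng.normal(150, 30, unit_cube.n_faces),
                  "wss": rng.uniform(0, 20, unit_cube.n_faces)}
        mesh = TriSurface(unit_cube.vertices, unit_cube.faces, fields)
        path = tmp_path / "cube.vtk"
        write_surface(mesh, path)
        back = read_surface(path)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)
        np.testing.assert_array_equal(back.faces, mesh.faces)
        for name in fields:
            np.testing.assert_array_equal(back.face_fields[name],
                                          mesh.face_fields[name])

    def test_point_data_averaged_to_faces(self, unit_cube, tmp_path):
        path = tmp_path / "pd.vtk"
        write_surface(unit_cube, path)
        with open(path, "a") as fh:
            fh.write(f"POINT_DATA {len(unit_cube.vertices)}\n"
                     "SCALARS pressure double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join("3.0" for _ in unit_cube.vertices) + "\n")
        back = read_surface(path)
        assert np.allclose(back.face_fields["pressure"], 3.0)

    def test_field_length_mismatch_is_error(self, unit_cube, tmp_path):
        path = tmp_path / "bad.vtk"
        write_surface(unit_cube, path)
        with open(path, "a") as fh:
            fh.write("CELL_DATA 5\nSCALARS pressure double 1\n"
                     "LOOKUP_TABLE default\n1 2 3 4 5\n")
        with pytest.raises(VtkParseError, match="pressure"):
            read_surface(path)

    def test_malformed_file_names_location(self, tmp_path):
        path = tmp_path / "junk.vtk"
        path.write_text("# vtk DataFile Version 3.0\nt\nASCII\n"
                        "DATASET POLYDATA\nPOINTS nope float\n")
        with pytest.raises(VtkParseError, match=r":\d+:"):
            read_surface(path)


class TestTriSurfaceInvariants:
    def test_degenerate_faces_dropped(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        m = TriSurface(v, np.array([[0, 1, 2], [0, 1, 1]]),
                       {"x": np.array([1.0, 2.0])})
        assert m.n_faces == 1
        assert m.face_fields["x"].tolist() == [1.0]

    def test_bad_face_index_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            TriSurface(np.zeros((3, 3)), np.array([[0, 1, 7]]))

    @given(st.floats(0.1, 10.0))
    def test_volume_scales_cubically(self, scale):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        m = TriSurface(box.vertices * scale, box.faces).oriented()
        assert enclosed_volume(m) == pytest.approx(scale ** 3, rel=1e-9)
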