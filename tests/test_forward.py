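"""Lead fields: sphere fitting, Sarvas model, corrected-sphere shell."""

import numpy as np
import pytest
import trimesh

from opmarray.forward import (HeadModel, SourceSpace, fit_sphere,
                              leadfield_single_shell, leadfield_sphere)
from opmarray.geometry import Sensor, SensorArray, RigidTransform, apply_pose

MU0_OVER_4PI = 1e-7


def sarvas_reference(sensor_pos, sensor_ori, source_pos, moment, centre):
    """Independent literal transcription of the conducting-sphere field.

    Scalar loop implementation kept deliberately separate from the
    vectorised production code: r and r0 relative to the sphere centre,
    a = r - r0, F = a(ra + r^2 - r0.r), and

        B = mu0/(4 pi F^2) (F (Q x r0) - (Q x r0 . r) grad F).
    """
    r = np.asarray(sensor_pos, float) - centre
    r0 = np.asarray(source_pos, float) - centre
    q = np.asarray(moment, float)
    a_vec = r - r0
    a = np.sqrt(a_vec @ a_vec)
    rn = np.sqrt(r @ r)
    F = a * (rn * a + rn**2 - r0 @ r)
    gradF = (a**2 / rn + (a_vec @ r) / a + 2 * a + 2 * rn) * r \
        - (a + 2 * rn + (a_vec @ r) / a) * r0
    B = MU0_OVER_4PI / F**2 * (F * np.cross(q, r0)
                               - (np.cross(q, r0) @ r) * gradF)
    return B @ np.asarray(sensor_ori, float)


class TestFitSphere:
    def test_exact_sphere_recovery(self, sphere_mesh):
        head = fit_sphere(sphere_mesh)
        assert np.linalg.norm(head.centre) < 1e-6
        assert abs(head.radius - 0.08) < 1e-6

    def test_hemisphere_subset(self, sphere_mesh):
        region = np.where(sphere_mesh.vertices[:, 2] > 0)[0]
        head = fit_sphere(sphere_mesh, region=region)
        assert np.linalg.norm(head.centre) < 1e-6
        assert abs(head.radius - 0.08) < 1e-6

    def test_ellipsoid_global_vs_local(self):
        base = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        verts = base.vertices * np.array([0.07, 0.08, 0.09])
        glob = fit_sphere(verts)
        # local fit over the top half (curvature differs from the global)
        region = np.where(verts[:, 2] > 0.04)[0]
        loc = fit_sphere(verts, region=region, kind="sphere_local")
        assert 0.07 <= glob.radius <= 0.09
        # a patch fit tracks local curvature: between the principal
        # curvature radii at the 0.09 pole (0.054 and 0.071) and the axes
        assert 0.05 <= loc.radius <= 0.09
        assert abs(glob.radius - loc.radius) > 1e-4

    def test_coplanar_failure(self):
        pts = np.random.default_rng(0).normal(size=(30, 2))
        verts = np.column_stack([pts, np.zeros(30)])
        with pytest.raises(ValueError):
            fit_sphere(verts)


class TestSarvasSphere:
    def test_radial_dipole_is_silent(self, cap_array, sphere_head):
        u = np.random.default_rng(3).normal(size=(20, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        src = SourceSpace(u * 0.06, u)  # moment parallel to radius
        lf = leadfield_sphere(cap_array, src, sphere_head)
        assert np.abs(lf.matrix).max() <= 1e-25

    def test_source_at_centre_silent(self, cap_array, sphere_head):
        src = SourceSpace([[0.0, 0.0, 0.0]], [[1.0, 0.0, 0.0]])
        lf = leadfield_sphere(cap_array, src, sphere_head)
        assert np.abs(lf.matrix).max() <= 1e-25

    def test_gain_linearity(self, cap_array, tangential_sources,
                            sphere_head):
        lf = leadfield_sphere(cap_array, tangential_sources, sphere_head)
        gains = cap_array.gains.copy()
        gains[4] *= 2.0
        doubled = cap_array.replace_geometry(gains=gains)
        lf2 = leadfield_sphere(doubled, tangential_sources, sphere_head)
        assert np.allclose(lf2.matrix[4], 2.0 * lf.matrix[4], rtol=1e-14)
        others = np.arange(13) != 4
        assert np.array_equal(lf2.matrix[others], lf.matrix[others])

    def test_against_independent_transcription(self, cap_array,
                                               tangential_sources,
                                               sphere_head):
        lf = leadfield_sphere(cap_array, tangential_sources, sphere_head)
        for c in range(len(cap_array)):
            for d in range(0, tangential_sources.n_sources, 7):
                ref = sarvas_reference(cap_array.positions[c],
                                       cap_array.orientations[c],
                                       tangential_sources.positions[d],
                                       tangential_sources.orientations[d],
                                       sphere_head.centre)
                assert lf.matrix[c, d] == pytest.approx(ref, rel=1e-12)

    def test_superposition_in_moment(self, cap_array, sphere_head):
        pos = np.array([0.01, 0.02, 0.05])
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, 1.0, 0.0])
        w = (u + v) / np.linalg.norm(u + v)
        cols = {}
        for name, ori in [("u", u), ("v", v), ("w", w)]:
            src = SourceSpace([pos], [ori])
            cols[name] = leadfield_sphere(cap_array, src,
                                          sphere_head).matrix[:, 0]
        expected = (cols["u"] + cols["v"]) / np.sqrt(2.0)
        assert np.allclose(cols["w"], expected, rtol=1e-12)

    def test_field_decays_with_source_depth(self, sphere_head):
        sensor = SensorArray((Sensor([0, 0, 0.0965], [0, 0, 1.0], 1.0,
                                     "s"),))
        norms = []
        for depth in (0.07, 0.06, 0.05, 0.04, 0.02):
            src = SourceSpace([[0.0, 0.0, depth]], [[1.0, 0.0, 0.0]])
            lf = leadfield_sphere(sensor, src, sphere_head)
            norms.append(abs(lf.matrix[0, 0]))
        assert np.all(np.diff(norms) < 0)

    def test_global_rigid_invariance(self, cap_array, tangential_sources,
                                     sphere_head):
        lf = leadfield_sphere(cap_array, tangential_sources, sphere_head)
        pose = RigidTransform([0.2, -0.1, 0.3], [0.01, 0.02, -0.01])
        arr2 = apply_pose(cap_array, pose)
        rot = pose.rotation
        src2 = SourceSpace(
            rot.apply(tangential_sources.positions) + pose.translation,
            rot.apply(tangential_sources.orientations))
        head2 = HeadModel("sphere_global",
                          rot.apply(sphere_head.centre) + pose.translation,
                          sphere_head.radius)
        lf2 = leadfield_sphere(arr2, src2, head2)
        assert np.allclose(lf2.matrix, lf.matrix, rtol=1e-10, atol=1e-25)

    def test_source_outside_sphere_warns(self, cap_array, sphere_head):
        src = SourceSpace([[0.0, 0.0, 0.09]], [[1.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="outside"):
            leadfield_sphere(cap_array, src, sphere_head)


class TestSingleShell:
    def test_spherical_shell_matches_sphere(self, cap_array,
                                            tangential_sources,
                                            sphere_mesh, sphere_head):
        ref = leadfield_sphere(cap_array, tangential_sources, sphere_head)
        shell = HeadModel("single_shell", sphere_head.centre,
                          shell_mesh=sphere_mesh, sh_order=8)
        lf = leadfield_single_shell(cap_array, tangential_sources, shell)
        rel = np.linalg.norm(lf.matrix - ref.matrix) \
            / np.linalg.norm(ref.matrix)
        assert rel < 0.005

    def test_radial_dipole_nearly_silent_in_spherical_shell(
            self, cap_array, sphere_mesh):
        pos = np.array([0.015, -0.01, 0.055])
        radial = pos / np.linalg.norm(pos)
        tang = np.cross(radial, [0, 0, 1.0])
        tang /= np.linalg.norm(tang)
        shell = HeadModel("single_shell", np.zeros(3),
                          shell_mesh=sphere_mesh, sh_order=8)
        lf_r = leadfield_single_shell(cap_array,
                                      SourceSpace([pos], [radial]), shell)
        lf_t = leadfield_single_shell(cap_array,
                                      SourceSpace([pos], [tang]), shell)
        assert np.linalg.norm(lf_r.matrix) < 0.01 * np.linalg.norm(
            lf_t.matrix)

    def test_order_convergence_on_ellipsoid(self, cap_array):
        base = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        ell = trimesh.Trimesh(
            base.vertices * np.array([0.076, 0.08, 0.084]), base.faces,
            process=False)
        rng = np.random.default_rng(2)
        u = rng.normal(size=(40, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        ori = np.cross(u, rng.normal(size=(40, 3)))
        ori /= np.linalg.norm(ori, axis=1, keepdims=True)
        src = SourceSpace(u * 0.05, ori)
        mats = {}
        for order in (6, 10):
            head = HeadModel("single_shell", np.zeros(3), shell_mesh=ell,
                             sh_order=order)
            mats[order] = leadfield_single_shell(cap_array, src, head).matrix
        rel = np.linalg.norm(mats[6] - mats[10]) / np.linalg.norm(mats[10])
        assert rel < 0.01

    def test_open_mesh_rejected(self, cap_array, tangential_sources,
                                sphere_mesh):
        open_mesh = trimesh.Trimesh(
            sphere_mesh.vertices,
            sphere_mesh.faces[:-20], process=False)
        head = HeadModel("single_shell", np.zeros(3), shell_mesh=open_mesh)
        with pytest.raises(ValueError, match="closed"):
            leadfield_single_shell(cap_array, tangential_sources, head)
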