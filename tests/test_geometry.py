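"""Geometry: meshing, septum detection, AHA partition, fibers, volumes."""

import numpy as np
import pytest

from lvmech import geometry as G
from lvmech.geometry import (
    IdealizedGeometry,
    MeshDensity,
    assign_fibers,
    cavity_volume,
    detect_septum,
    fiber_at,
    generate_idealized_lv,
    make_rv_endo_shell,
    partition_aha17,
    septal_wedge_facets,
)


class TestMeshGeneration:
    def test_element_count_matches_density(self):
        dens = MeshDensity(3, 40, 22)
        mesh = generate_idealized_lv(IdealizedGeometry(), dens)
        assert dens.n_body == 3 * 40 * 22 == 2640
        assert mesh.n_elements == dens.n_elements == 2640 + 3 * 10 * 10

    def test_minimal_density_mesh_is_valid(self):
        mesh = generate_idealized_lv(IdealizedGeometry(), MeshDensity(1, 4, 2))
        assert mesh.jacobians().min() > 0.0

    def test_endocardial_nodes_lie_on_the_endocardial_ellipsoid(self):
        geom = IdealizedGeometry(a_endo=25, c_endo=60, wall_thickness=10)
        mesh = generate_idealized_lv(geom, MeshDensity(2, 16, 8))
        ids = np.unique(mesh.facet_sets["endo"].reshape(-1))
        p = mesh.nodes[ids]
        resid = (
            (p[:, 0] ** 2 + p[:, 1] ** 2) / geom.a_endo**2
            + (p[:, 2] - geom.z_center) ** 2 / geom.c_endo**2
        )
        assert np.abs(resid - 1.0).max() < 1e-9

    def test_facet_sets_disjoint_and_base_on_truncation_plane(self, mesh_ci):
        endo = {tuple(sorted(q)) for q in mesh_ci.facet_sets["endo"]}
        epi = {tuple(sorted(q)) for q in mesh_ci.facet_sets["epi"]}
        assert not endo & epi
        base_nodes = np.unique(mesh_ci.facet_sets["base"].reshape(-1))
        assert np.abs(mesh_ci.nodes[base_nodes, 2]).max() < 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            IdealizedGeometry(a_endo=-1.0)
        with pytest.raises(ValueError):
            MeshDensity(0, 12, 6)
        with pytest.raises(ValueError):
            MeshDensity(1, 10, 6)  # circumference not divisible by 4


class TestCavityVolume:
    def test_half_ellipsoid_closed_form(self):
        geom = IdealizedGeometry(a_endo=25, c_endo=60, truncation=0.0)
        mesh = generate_idealized_lv(geom, MeshDensity(3, 40, 22))
        exact = 2.0 / 3.0 * np.pi * 25 * 25 * 60 / 1000.0
        assert abs(cavity_volume(mesh) - exact) / exact < 0.01

    def test_translation_invariance(self, mesh_ci):
        v0 = cavity_volume(mesh_ci)
        shift = np.tile([13.0, -7.0, 0.0], (mesh_ci.n_nodes, 1))
        assert abs(cavity_volume(mesh_ci, shift) - v0) / v0 < 1e-10

    def test_uniform_scaling_scales_volume_cubically(self, mesh_ci):
        v0 = cavity_volume(mesh_ci)
        k = 1.3
        disp = (k - 1.0) * mesh_ci.nodes
        assert abs(cavity_volume(mesh_ci, disp) - k**3 * v0) / v0 < 1e-10

    def test_volume_converges_with_observed_order_at_least_one(self):
        geom = IdealizedGeometry(a_endo=25, c_endo=60, truncation=0.0)
        exact = 2.0 / 3.0 * np.pi * 25 * 25 * 60 / 1000.0
        errs = []
        for nc, nl in [(8, 4), (16, 8), (32, 16)]:
            mesh = generate_idealized_lv(geom, MeshDensity(1, nc, nl))
            errs.append(abs(cavity_volume(mesh) - exact) / exact)
        order1 = np.log2(errs[0] / errs[1])
        order2 = np.log2(errs[1] / errs[2])
        assert min(order1, order2) >= 1.0


class TestSeptum:
    def test_rv_shell_on_minus_x_yields_facets_with_negative_x_normals(self, mesh_ci):
        quads = mesh_ci.facet_sets["septal_epi"]
        pts = mesh_ci.nodes[quads]
        nrm = np.cross(pts[:, 2] - pts[:, 0], pts[:, 3] - pts[:, 1])
        assert len(quads) > 0
        assert (nrm[:, 0] < 0).all()

    def test_far_rv_surface_gives_empty_set(self):
        geom = IdealizedGeometry()
        mesh = generate_idealized_lv(geom, MeshDensity(1, 8, 4))
        verts, faces = make_rv_endo_shell(geom, gap=50.0)
        assert len(detect_septum(mesh, (verts, faces), max_distance=10.0)) == 0

    def test_empty_rv_surface_raises_with_fallback_hint(self, mesh_ci):
        with pytest.raises(ValueError, match="wedge"):
            detect_septum(mesh_ci, (np.zeros((0, 3)), np.zeros((0, 3), int)))

    def test_wedge_fallback_selects_the_requested_azimuth_range(self):
        geom = IdealizedGeometry()
        mesh = generate_idealized_lv(geom, MeshDensity(1, 12, 6))
        idx = septal_wedge_facets(mesh, wedge=(120.0, 240.0))
        cen = mesh.nodes[mesh.facet_sets["epi"][idx]].mean(axis=1)
        az = np.degrees(np.arctan2(cen[:, 1], cen[:, 0])) % 360.0
        assert len(idx) > 0
        assert ((az >= 120.0) & (az <= 240.0)).all()

    def test_detection_invariant_under_joint_rigid_rotation(self):
        geom = IdealizedGeometry()
        mesh = generate_idealized_lv(geom, MeshDensity(1, 12, 6))
        verts, faces = make_rv_endo_shell(geom)
        ref = set(detect_septum(mesh, (verts, faces)))
        ang = 0.77
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        mesh.nodes = mesh.nodes @ R.T
        rot = set(detect_septum(mesh, (verts @ R.T, faces)))
        assert rot == ref


class TestAhaPartition:
    def test_reference_mesh_carries_all_17_sectors(self, mesh_ci):
        assert set(np.unique(mesh_ci.element_sector)) == set(range(1, 18))

    def test_apex_cap_is_exactly_sector_17(self, mesh_ci):
        assert (mesh_ci.element_sector[mesh_ci.is_cap] == 17).all()
        assert (mesh_ci.element_sector[~mesh_ci.is_cap] != 17).all()

    def test_centroid_on_circumferential_boundary_takes_lower_sector(self):
        # a value exactly on a wedge boundary takes the lower-numbered of the
        # two sectors meeting there (including across the 6 -> 1 wrap)
        psi = np.array([0.0, 60.0, 120.0, 240.0, 300.0])
        labels = G._ring_sector(psi, 6, 0.0, 0)
        # wedges: [0,60)->2, [60,120)->3 ... boundary values pick the smaller
        assert labels.tolist() == [1, 2, 3, 5, 1]
        mid = G._ring_sector(np.array([60.0]), 6, 0.0, 6)
        assert mid.tolist() == [8]
        inner = G._ring_sector(np.array([90.0]), 6, 0.0, 0)
        assert inner.tolist() == [3]

    def test_sector_populations_balanced_when_commensurate(self, mesh_ci):
        # sector boundaries sit on facet node lines, so with 12 elements per
        # ring every basal/mid sector holds the same number of elements
        counts = [
            (mesh_ci.element_sector == s).sum() for s in range(1, 7)
        ]
        assert len(set(counts)) == 1

    def test_too_coarse_mesh_warns_about_empty_sectors(self):
        geom = IdealizedGeometry()
        mesh = generate_idealized_lv(geom, MeshDensity(1, 4, 2))
        idx = septal_wedge_facets(mesh)
        with pytest.warns(UserWarning, match="sectors"):
            partition_aha17(mesh, idx)


class TestFibers:
    def test_helix_angle_rule_endo_mid_epi(self, mesh_ci):
        eids = np.array([0, 0, 0])
        t = np.array([0.0, 0.5, 1.0])
        f = fiber_at(mesh_ci, t, eids)
        e_c = mesh_ci.element_frame_c[0]
        e_l = mesh_ci.element_frame_l[0]
        ang = np.degrees(np.arctan2(f @ e_l, f @ e_c))
        assert ang == pytest.approx([60.0, 0.0, -60.0], abs=1e-9)
        assert np.allclose(f[1], e_c)

    def test_fiber_field_unit_norm_and_tangent_to_wall(self, mesh_ci):
        f = mesh_ci.fiber_vector
        assert np.abs(np.linalg.norm(f, axis=1) - 1.0).max() < 1e-12
        assert np.abs(np.einsum("ei,ei->e", f, mesh_ci.element_frame_r)).max() < 1e-12

    def test_missing_frames_raise_state_error(self):
        mesh = generate_idealized_lv(IdealizedGeometry(), MeshDensity(1, 4, 2))
        mesh.element_frame_c = None
        with pytest.raises(RuntimeError, match="frames"):
            assign_fibers(mesh)
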