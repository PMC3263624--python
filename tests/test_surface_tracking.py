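"""Surface-landmark tracking: distance maps, active surfaces, ICP, smoothing."""

import numpy as np
import pytest

from brainshift_xfem.core_mesh import LabelImage3D, TriSurface, extract_boundary_surface
from brainshift_xfem.surface_tracking import (
    active_surface_evolve,
    compute_distance_map,
    local_rigid_icp_prealign,
    smooth_displacement_knn,
    transfer_to_mesh_boundary,
)

from conftest import make_sphere_labels


def sphere_label_mask(n, spacing, radius):
    idx = np.indices((n, n, n)).astype(float)
    c = (n - 1) / 2.0
    r = np.sqrt(((idx - c) ** 2).sum(axis=0)) * spacing
    lab = np.zeros((n, n, n), dtype=np.int32)
    lab[r < radius] = 1
    return LabelImage3D(lab, spacing=(spacing,) * 3)


class TestDistanceMap:
    def test_boundary_voxels_are_zero(self):
        lab = sphere_label_mask(32, 1.0, 10.0)
        dm = compute_distance_map(lab, "healthy_brain")
        from scipy import ndimage
        mask = lab.region_mask("healthy_brain")
        bnd = mask & ~ndimage.binary_erosion(mask)
        assert np.all(dm.values[bnd] == 0)

    def test_one_step_from_flat_boundary(self):
        lab = np.zeros((8, 8, 8), dtype=np.int32)
        lab[:4] = 1  # half-space; boundary voxels at i = 3
        L = LabelImage3D(lab, spacing=(0.9375, 1.0, 1.0))
        dm = compute_distance_map(L, "healthy_brain")
        assert dm.values[2, 4, 4] == pytest.approx(0.9375)
        assert dm.values[4, 4, 4] == pytest.approx(0.9375)

    def test_matches_brute_force_on_random_blobs(self, rng):
        lab = (rng.random((16, 16, 16)) < 0.1).astype(np.int32)
        lab[8, 8, 8] = 1
        from scipy import ndimage
        lab = ndimage.binary_dilation(lab).astype(np.int32)
        L = LabelImage3D(lab, spacing=(1.0, 1.5, 2.0))
        dm = compute_distance_map(L, "healthy_brain")
        mask = L.region_mask("healthy_brain")
        bnd = mask & ~ndimage.binary_erosion(mask)
        bpts = np.argwhere(bnd) * np.array([1.0, 1.5, 2.0])
        pts = np.indices((16, 16, 16)).reshape(3, -1).T * np.array([1.0, 1.5, 2.0])
        brute = np.sqrt(((pts[:, None, :] - bpts[None]) ** 2).sum(-1)).min(1)
        assert np.allclose(dm.values.ravel(), brute, atol=1e-9)

    def test_empty_region_errors(self):
        L = LabelImage3D(np.zeros((4, 4, 4), dtype=np.int32))
        with pytest.raises(ValueError, match="empty"):
            compute_distance_map(L, "healthy_brain")

    def test_lipschitz_bound(self):
        lab = sphere_label_mask(24, 1.0, 8.0)
        dm = compute_distance_map(lab, "healthy_brain")
        for ax in range(3):
            d = np.abs(np.diff(dm.values, axis=ax))
            assert d.max() <= 1.0 + 1e-9


class TestActiveSurface:
    def _sphere_surface(self, radius, center, n_sub=20):
        lab = sphere_label_mask(48, 1.0, radius)
        from brainshift_xfem.core_mesh import tetrahedralize_labeled_grid
        mesh = tetrahedralize_labeled_grid(lab, 2.0)
        surf = extract_boundary_surface(mesh, "all")
        return surf

    def test_on_boundary_surface_barely_moves(self):
        # flat boundary with a surface patch exactly on the zero set
        lab = np.zeros((12, 12, 12), dtype=np.int32)
        lab[:6] = 1  # boundary voxels at i = 5
        dm = compute_distance_map(LabelImage3D(lab), "healthy_brain")
        yz = np.stack(np.meshgrid(np.arange(3.0, 9.0), np.arange(3.0, 9.0)), -1)
        v = np.concatenate([np.full(yz.shape[:2] + (1,), 5.0), yz], axis=-1).reshape(-1, 3)
        tris = []
        for i in range(5):
            for j in range(5):
                a = i * 6 + j
                tris.extend([[a, a + 1, a + 6], [a + 1, a + 7, a + 6]])
        surf = TriSurface(v, np.array(tris))
        out = active_surface_evolve(surf, dm, alpha_internal=0.0, max_iters=50, tol=1e-3)
        motion = np.linalg.norm(out.vertices - surf.vertices, axis=1)
        assert motion.max() < 1e-3

    def test_sphere_grows_to_target_radius(self):
        small = self._sphere_surface(15.0, None)
        target_lab = sphere_label_mask(48, 1.0, 20.0)
        dm = compute_distance_map(target_lab, "healthy_brain")
        out = active_surface_evolve(small, dm, alpha_internal=0.1, max_iters=400)
        c = out.vertices.mean(axis=0)
        r = np.linalg.norm(out.vertices - c, axis=1)
        assert abs(r.mean() - 20.0) < 1.0  # within one voxel

    def test_pure_descent_moves_downhill_in_ramp(self):
        from brainshift_xfem.surface_tracking import DistanceMap
        ramp = np.tile(np.arange(16.0)[:, None, None], (1, 16, 16))
        dm = DistanceMap(ramp, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        tri = TriSurface(np.array([[8.0, 8.0, 8.0], [8.0, 9.0, 8.0], [8.0, 8.0, 9.0]]),
                         np.array([[0, 1, 2]]))
        out = active_surface_evolve(tri, dm, step=0.1, alpha_internal=0.0, max_iters=5,
                                    tol=0.0)
        moved = out.vertices - tri.vertices
        assert np.all(moved[:, 0] < 0)           # down the +x ramp
        assert np.abs(moved[:, 1:]).max() < 1e-9  # straight downhill


class TestICP:
    def test_recovers_translation(self):
        lab = make_sphere_labels()
        from brainshift_xfem.core_mesh import tetrahedralize_labeled_grid
        mesh = tetrahedralize_labeled_grid(lab, 2.0)
        surf = extract_boundary_surface(mesh, "tumor")
        target = TriSurface(surf.vertices + np.array([5.0, 0.0, 0.0]),
                            surf.triangles.copy())
        t = local_rigid_icp_prealign(surf, target)
        assert np.linalg.norm(t.translation - [5.0, 0.0, 0.0]) < 0.1
        err = np.linalg.norm(t.apply(surf.vertices) - target.vertices, axis=1)
        assert err.max() < 0.1

    def test_identity_case(self):
        lab = make_sphere_labels()
        from brainshift_xfem.core_mesh import tetrahedralize_labeled_grid
        mesh = tetrahedralize_labeled_grid(lab, 2.0)
        surf = extract_boundary_surface(mesh, "tumor")
        t = local_rigid_icp_prealign(surf, surf)
        assert np.allclose(t.matrix(), np.eye(4), atol=1e-9)

    def test_degenerate_patch_errors(self):
        patch = TriSurface(np.zeros((2, 3)), np.zeros((0, 3), dtype=int))
        target = TriSurface(np.eye(3), [[0, 1, 2]])
        with pytest.raises(ValueError, match="degenerate"):
            local_rigid_icp_prealign(patch, target)


class TestKnnSmoothing:
    @pytest.fixture()
    def flat_surface(self, rng):
        xy = np.stack(np.meshgrid(np.arange(10.0), np.arange(10.0)), -1).reshape(-1, 2)
        xy += rng.normal(0, 0.05, xy.shape)  # break distance ties
        v = np.column_stack([xy, np.zeros(len(xy))])
        tris = []
        for i in range(9):
            for j in range(9):
                a = i * 10 + j
                tris.append([a, a + 1, a + 10])
                tris.append([a + 1, a + 11, a + 10])
        return TriSurface(v, np.array(tris))

    def test_constant_field_unchanged(self, flat_surface):
        d = np.tile([1.0, -2.0, 0.5], (flat_surface.n_vertices, 1))
        out = smooth_displacement_knn(d, flat_surface, 5)
        assert np.allclose(out, d, atol=1e-12)

    def test_spike_strictly_reduced(self, flat_surface):
        d = np.zeros((flat_surface.n_vertices, 3))
        d[45, 0] = 1.0
        out = smooth_displacement_knn(d, flat_surface, 5)
        assert 0 < out[45, 0] < 1.0
        # nearest neighbors gained a positive share
        assert out[44, 0] > 0 and out[46, 0] > 0

    def test_matches_brute_force_oracle(self, flat_surface, rng):
        d = rng.normal(size=(flat_surface.n_vertices, 3))
        N = 6
        out = smooth_displacement_knn(d, flat_surface, N)
        v = flat_surface.vertices
        for i in (0, 17, 55, 99):
            dist = np.linalg.norm(v - v[i], axis=1)
            order = np.argsort(dist, kind="stable")[: N + 1]
            dd = dist[order]
            dbar = dd[1:].mean()
            w = 1.0 / (dd + dbar / 2.0)
            w /= w.sum()
            assert np.allclose(out[i], w @ d[order], atol=1e-10)

    def test_contraction_of_deviation(self, flat_surface, rng):
        d = rng.normal(size=(flat_surface.n_vertices, 3))
        out = smooth_displacement_knn(d, flat_surface, 8)
        dev_in = np.abs(d - d.mean(0)).max()
        dev_out = np.abs(out - out.mean(0)).max()
        assert dev_out < dev_in

    def test_bad_neighbor_count_errors(self, flat_surface):
        d = np.zeros((flat_surface.n_vertices, 3))
        with pytest.raises(ValueError):
            smooth_displacement_knn(d, flat_surface, 0)


class TestTransfer:
    def test_mesh_boundary_itself_reproduces_displacements(self, sphere_mesh, rng):
        surf = extract_boundary_surface(sphere_mesh, "all")
        d = rng.normal(size=(surf.n_vertices, 3))
        bcs = transfer_to_mesh_boundary(d, surf, sphere_mesh, surf.boundary_node_ids)
        vals = np.stack([bcs.entries[int(n)] for n in surf.boundary_node_ids])
        assert np.allclose(vals, d, atol=1e-9)

    def test_constant_field_gives_constant_bcs(self, sphere_mesh):
        surf = extract_boundary_surface(sphere_mesh, "all")
        d = np.tile([1.0, 2.0, 3.0], (surf.n_vertices, 1))
        bcs = transfer_to_mesh_boundary(d, surf, sphere_mesh, surf.boundary_node_ids)
        for v in bcs.entries.values():
            assert np.allclose(v, [1.0, 2.0, 3.0], atol=1e-9)

    def test_smooth_field_interpolated_within_error(self, sphere_mesh):
        surf = extract_boundary_surface(sphere_mesh, "all")
        refined = TriSurface(surf.vertices.copy(), surf.triangles.copy())
        field = lambda x: np.stack(
            [0.01 * x[:, 0] + 0.002 * x[:, 1], 0.005 * x[:, 2], 0.01 * x[:, 1]], axis=1)
        d = field(refined.vertices)
        bcs = transfer_to_mesh_boundary(d, refined, sphere_mesh, surf.boundary_node_ids)
        ids = surf.boundary_node_ids
        expect = field(sphere_mesh.node_coords[ids])
        vals = np.stack([bcs.entries[int(n)] for n in ids])
        assert np.abs(vals - expect).max() < 1e-6  # affine field: exact interpolation

    def test_gap_violation_errors(self, sphere_mesh):
        surf = extract_boundary_surface(sphere_mesh, "all")
        far = TriSurface(surf.vertices + 100.0, surf.triangles.copy())
        d = np.zeros((far.n_vertices, 3))
        with pytest.raises(ValueError, match="farther"):
            transfer_to_mesh_boundary(d, far, sphere_mesh, surf.boundary_node_ids,
                                      max_gap=2.0)
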