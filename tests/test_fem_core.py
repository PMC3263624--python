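"""Linear-elastic FEM: element stiffness, assembly, Dirichlet solve, strains."""

import numpy as np
import pytest

from brainshift_xfem.core_mesh import MaterialLaw, TetMesh, extract_boundary_surface
from brainshift_xfem.fem_core import (
    BoundaryConditionSet,
    accumulate_increments,
    assemble_stiffness,
    element_stiffness,
    element_strain,
    shape_gradients,
    solve_dirichlet,
    solve_fem,
)

UNIT_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)


def quadrature_stiffness_oracle(coords, law, n_samples=2000, seed=0):
    """Independent stiffness: Monte-Carlo quadrature of B^T D B with
    shape-function gradients from finite differences of the barycentric
    interpolation (no reuse of the analytic B-matrix path)."""
    rng = np.random.default_rng(seed)
    M = np.vstack([coords.T, np.ones(4)])  # lambda(x): solve M lam = (x, 1)

    def lam(x):
        return np.linalg.solve(M, np.append(x, 1.0))

    # sample points uniformly in the tet
    b = rng.dirichlet(np.ones(4), size=n_samples)
    pts = b @ coords
    h = 1e-6
    D = law.hooke_voigt()
    vol = abs(np.linalg.det(coords[1:] - coords[0])) / 6.0
    K = np.zeros((12, 12))
    for p in pts:
        grads = np.zeros((4, 3))
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            grads[:, ax] = (lam(p + e) - lam(p - e)) / (2 * h)
        B = np.zeros((6, 12))
        for a in range(4):
            gx, gy, gz = grads[a]
            c = 3 * a
            B[0, c] = gx; B[1, c + 1] = gy; B[2, c + 2] = gz
            B[3, c + 1] = gz; B[3, c + 2] = gy
            B[4, c] = gz; B[4, c + 2] = gx
            B[5, c] = gy; B[5, c + 1] = gx
        K += B.T @ D @ B
    return K * vol / n_samples


class TestElementStiffness:
    def test_symmetric_psd_six_rigid_modes(self):
        K = element_stiffness(UNIT_TET, MaterialLaw())
        assert np.allclose(K, K.T)
        w = np.linalg.eigvalsh(K)
        assert np.all(w > -1e-8 * w.max())
        assert (np.abs(w) < 1e-9 * w.max()).sum() == 6

    def test_rigid_translation_gives_zero_forces(self):
        K = element_stiffness(UNIT_TET, MaterialLaw())
        u = np.tile([0.3, -0.2, 0.7], 4)
        assert np.abs(K @ u).max() < 1e-12 * np.abs(K).max()

    def test_small_rigid_rotation_gives_zero_forces(self):
        K = element_stiffness(UNIT_TET, MaterialLaw())
        W = np.array([[0, -1e-6, 2e-6], [1e-6, 0, -3e-6], [-2e-6, 3e-6, 0]])
        u = (UNIT_TET @ W.T).ravel()
        assert np.abs(K @ u).max() < 1e-10 * np.abs(K).max()

    def test_matches_quadrature_oracle(self):
        law = MaterialLaw(E=1.0, nu=0.0)
        K = element_stiffness(UNIT_TET, law)
        K_mc = quadrature_stiffness_oracle(UNIT_TET, law)
        # integrand is constant, so the MC oracle differs only by FD error
        assert np.abs(K - K_mc).max() < 1e-6

    def test_degenerate_tet_errors(self):
        flat = UNIT_TET.copy()
        flat[3] = [0.5, 0.5, 0.0]
        with pytest.raises(ValueError, match="degenerate"):
            element_stiffness(flat, MaterialLaw())


class TestAssembly:
    def test_one_tet_equals_element(self):
        mesh = TetMesh(UNIT_TET, [[0, 1, 2, 3]], [1])
        law = MaterialLaw()
        K = assemble_stiffness(mesh, law).toarray()
        assert np.allclose(K, element_stiffness(UNIT_TET, law))

    def test_two_tets_match_dense_oracle(self):
        coords = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], dtype=float)
        tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
        mesh = TetMesh(coords, tets, [1, 1])
        law = MaterialLaw()
        K = assemble_stiffness(mesh, law).toarray()
        dense = np.zeros((15, 15))
        for tet in tets:
            Ke = element_stiffness(coords[tet], law)
            dofs = np.concatenate([3 * v + np.arange(3) for v in tet])
            for i, gi in enumerate(dofs):
                for j, gj in enumerate(dofs):
                    dense[gi, gj] += Ke[i, j]
        assert np.allclose(K, dense)

    def test_dof_count_is_three_per_node(self, bar_mesh):
        K = assemble_stiffness(bar_mesh, MaterialLaw())
        assert K.shape == (3 * bar_mesh.n_nodes, 3 * bar_mesh.n_nodes)
        assert (K - K.T).nnz == 0 or abs((K - K.T)).max() == 0

    def test_energy_nonnegative(self, bar_mesh, rng):
        K = assemble_stiffness(bar_mesh, MaterialLaw())
        for _ in range(5):
            u = rng.normal(size=K.shape[0])
            assert u @ (K @ u) >= -1e-9 * np.abs(u).max() ** 2
        rigid = np.tile([1.0, -2.0, 0.5], bar_mesh.n_nodes)
        assert abs(rigid @ (K @ rigid)) < 1e-8


class TestDirichletSolve:
    def _affine(self, x):
        A = np.array([[0.1, 0.02, 0.0], [0.01, -0.05, 0.03], [0.0, 0.01, 0.08]])
        return x @ A.T + np.array([0.5, -0.2, 0.1])

    def test_patch_test_affine_field(self, bar_mesh):
        surf = extract_boundary_surface(bar_mesh, "all")
        bnodes = surf.boundary_node_ids
        bcs = BoundaryConditionSet()
        bcs.update(bnodes, self._affine(bar_mesh.node_coords[bnodes]))
        u = solve_fem(bar_mesh, MaterialLaw(), bcs)
        exact = self._affine(bar_mesh.node_coords)
        rel = np.abs(u - exact).max() / np.abs(exact).max()
        assert rel < 1e-8

    def test_solution_independent_of_young_modulus(self, bar_mesh):
        surf = extract_boundary_surface(bar_mesh, "all")
        bnodes = surf.boundary_node_ids
        bcs = BoundaryConditionSet()
        bcs.update(bnodes, self._affine(bar_mesh.node_coords[bnodes]))
        u1 = solve_fem(bar_mesh, MaterialLaw(E=3000.0, nu=0.45), bcs)
        u2 = solve_fem(bar_mesh, MaterialLaw(E=6000.0, nu=0.45), bcs)
        assert np.abs(u1 - u2).max() <= 1e-10 * max(np.abs(u1).max(), 1e-30)

    def test_axial_bar_linear_profile(self, bar_mesh):
        x = bar_mesh.node_coords
        L = x[:, 0].max()
        left = np.nonzero(x[:, 0] < 1e-9)[0]
        right = np.nonzero(x[:, 0] > L - 1e-9)[0]
        bcs = BoundaryConditionSet()
        bcs.update(left, np.zeros((len(left), 3)))
        bcs.update(right, np.tile([0.1, 0.0, 0.0], (len(right), 1)))
        u = solve_fem(bar_mesh, MaterialLaw(E=1000.0, nu=0.0), bcs)
        # nu = 0 uncouples the axes: u_x = 0.1 x / L, u_y = u_z = 0
        assert np.abs(u[:, 0] - 0.1 * x[:, 0] / L).max() < 1e-8
        assert np.abs(u[:, 1:]).max() < 1e-8

    def test_floating_structure_errors(self, bar_mesh):
        K = assemble_stiffness(bar_mesh, MaterialLaw())
        with pytest.raises(ValueError, match="floating"):
            solve_dirichlet(K, BoundaryConditionSet())


class TestStrain:
    def test_rigid_motion_zero_strain(self, bar_mesh):
        u = np.tile([1.0, 2.0, -0.5], (bar_mesh.n_nodes, 1))
        eps = element_strain(bar_mesh, u)
        assert np.abs(eps).max() < 1e-12

    def test_uniform_stretch(self, bar_mesh):
        lam = 0.01
        u = np.zeros((bar_mesh.n_nodes, 3))
        u[:, 0] = lam * bar_mesh.node_coords[:, 0]
        eps = element_strain(bar_mesh, u)
        assert np.allclose(eps[:, 0, 0], lam)
        assert np.abs(eps[:, 1:, :]).max() < 1e-12

    def test_random_field_matches_fd_oracle(self, bar_mesh, rng):
        u = rng.normal(0, 0.1, (bar_mesh.n_nodes, 3))
        eps = element_strain(bar_mesh, u)
        # finite-difference oracle on one tet via barycentric interpolation
        t = 17
        tet = bar_mesh.tets[t]
        coords = bar_mesh.node_coords[tet]
        M = np.vstack([coords.T, np.ones(4)])

        def u_at(x):
            lamv = np.linalg.solve(M, np.append(x, 1.0))
            return lamv @ u[tet]

        c = coords.mean(axis=0)
        h = 1e-6
        grad = np.zeros((3, 3))
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            grad[:, ax] = (u_at(c + e) - u_at(c - e)) / (2 * h)
        eps_fd = 0.5 * (grad + grad.T)
        assert np.abs(eps[t] - eps_fd).max() < 1e-6

    def test_misaligned_field_errors(self, bar_mesh):
        with pytest.raises(ValueError, match="aligned"):
            element_strain(bar_mesh, np.zeros((3, 3)))


class TestSuperposition:
    def test_sum_of_field_and_negation_is_zero(self, rng):
        f = rng.normal(size=(10, 3))
        assert np.abs(accumulate_increments([f, -f])).max() == 0

    def test_single_field_identity(self, rng):
        f = rng.normal(size=(10, 3))
        assert np.array_equal(accumulate_increments([f]), f)

    def test_two_increments_equal_combined_solve(self, bar_mesh, rng):
        surf = extract_boundary_surface(bar_mesh, "all")
        bnodes = surf.boundary_node_ids
        d1 = rng.normal(0, 0.05, (len(bnodes), 3))
        d2 = rng.normal(0, 0.05, (len(bnodes), 3))
        law = MaterialLaw()
        K = assemble_stiffness(bar_mesh, law)

        def solve(d):
            bcs = BoundaryConditionSet()
            bcs.update(bnodes, d)
            return solve_dirichlet(K, bcs)

        u_sum = accumulate_increments([solve(d1), solve(d2)])
        u_comb = solve(d1 + d2)
        scale = np.abs(u_comb).max()
        assert np.abs(u_sum - u_comb).max() < 1e-10 * scale

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError, match="mismatched"):
            accumulate_increments([np.zeros((4, 3)), np.zeros((5, 3))])
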