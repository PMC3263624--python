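"""XFEM: enrichment functions, cut-element quadrature, enriched solves."""

import warnings

import numpy as np
import pytest

from brainshift_xfem.core_mesh import MaterialLaw, TriSurface
from brainshift_xfem.fem_core import BoundaryConditionSet, assemble_stiffness, element_strain
from brainshift_xfem.xfem_core import (
    HEAVISIDE,
    HOLE,
    CrackSurface,
    OnCrackError,
    build_enrichment,
    enrichment_function,
    evaluate_displacement,
    split_tet_by_levelset,
    subdivide_cut_tet,
    xfem_assemble,
    xfem_assemble_solve,
)

from conftest import make_bar_mesh


def plane_crack(x0, normal_axis=0, extent=10.0):
    """Large planar square crack at coordinate x0 along one axis."""
    n = np.zeros(3)
    n[normal_axis] = 1.0
    # two in-plane directions
    a = np.zeros(3); a[(normal_axis + 1) % 3] = 1.0
    b = np.zeros(3); b[(normal_axis + 2) % 3] = 1.0
    c = x0 * n
    v = np.array([c - extent * a - extent * b, c + extent * a - extent * b,
                  c + extent * a + extent * b, c - extent * a + extent * b])
    # winding chosen so the normal points along +axis
    return CrackSurface(TriSurface(v, [[0, 1, 2], [0, 2, 3]]), closed=False)


UNIT_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)


class TestEnrichmentFunction:
    def test_heaviside_signs(self):
        crack = plane_crack(0.0, normal_axis=2)
        assert enrichment_function([0, 0, 1.0], crack, HEAVISIDE) == 1.0
        assert enrichment_function([0, 0, -1.0], crack, HEAVISIDE) == -1.0

    def test_flipped_normal_flips_sign(self):
        crack = plane_crack(0.0, normal_axis=2)
        assert enrichment_function([0, 0, 1.0], crack.flipped(), HEAVISIDE) == -1.0

    def test_hole_function_zeroes_negative_side(self):
        crack = plane_crack(0.0, normal_axis=2)
        assert enrichment_function([0, 0, -1.0], crack, HOLE) == 0.0
        assert enrichment_function([0, 0, 1.0], crack, HOLE) == 1.0

    def test_on_crack_raises(self):
        crack = plane_crack(0.0, normal_axis=2)
        with pytest.raises(OnCrackError):
            enrichment_function([0.5, 0.5, 0.0], crack, HEAVISIDE)


class TestBuildEnrichment:
    def test_crack_outside_mesh_empty_table(self, bar_mesh):
        crack = plane_crack(50.0)
        table = build_enrichment(bar_mesh, crack, HEAVISIDE)
        assert table.n_enriched == 0
        assert not table.cut_tets

    def test_bar_mid_plane_enriches_adjacent_layers(self):
        mesh = make_bar_mesh(nx=8, ny=4, nz=4, pitch=0.25)  # layers at 0, .25, ... 1.75
        crack = plane_crack(0.875)
        table = build_enrichment(mesh, crack, HEAVISIDE)
        x = mesh.node_coords[:, 0]
        expected = np.nonzero((np.abs(x - 0.75) < 1e-9) | (np.abs(x - 1.0) < 1e-9))[0]
        assert set(table.enriched_nodes.tolist()) == set(expected.tolist())

    def test_enriched_node_has_six_dofs(self):
        mesh = make_bar_mesh(nx=8, ny=4, nz=4, pitch=0.25)
        table = build_enrichment(mesh, plane_crack(0.875), HEAVISIDE)
        enriched = int(table.enriched_nodes[0])
        plain = int(np.setdiff1d(np.arange(mesh.n_nodes), table.enriched_nodes)[0])
        assert table.dofs_of_node(enriched) == 6
        assert table.dofs_of_node(plain) == 3
        assert table.total_dofs == 3 * mesh.n_nodes + 3 * table.n_enriched


class TestCutSubdivision:
    def test_plane_through_midpoints_four_subtets(self):
        d = np.array([-1.0, 1.0, 1.0, 1.0])  # cuts the three edges at vertex 0
        sub = split_tet_by_levelset(UNIT_TET, d)
        assert len(sub) == 4
        vols = sum(abs(np.linalg.det(s[1:] - s[0])) / 6.0 for s, _ in sub)
        assert vols == pytest.approx(1.0 / 6.0, rel=1e-14)

    def test_two_two_split_conserves_volume(self):
        d = np.array([1.0, 1.0, -1.0, -1.0])
        sub = split_tet_by_levelset(UNIT_TET, d)
        assert len(sub) == 6
        vols = sum(abs(np.linalg.det(s[1:] - s[0])) / 6.0 for s, _ in sub)
        assert vols == pytest.approx(1.0 / 6.0, rel=1e-14)

    def test_random_cuts_conserve_volume(self, rng):
        parent = 1.0 / 6.0
        for _ in range(1000):
            d = rng.normal(size=4)
            sub = split_tet_by_levelset(UNIT_TET, d)
            vols = sum(abs(np.linalg.det(s[1:] - s[0])) / 6.0 for s, _ in sub)
            assert abs(vols - parent) <= 1e-12 * parent
            for s, side in sub:
                assert side in (-1, 1)

    def test_missing_plane_single_subcell(self):
        sub = split_tet_by_levelset(UNIT_TET, np.array([1.0, 2.0, 3.0, 4.0]))
        assert len(sub) == 1
        assert sub[0][1] == 1

    def test_subdivide_against_crack_geometry(self):
        crack = plane_crack(0.2, normal_axis=2, extent=5.0)
        sub = subdivide_cut_tet(UNIT_TET, crack)
        vols = sum(abs(np.linalg.det(s[1:] - s[0])) / 6.0 for s, _ in sub)
        assert vols == pytest.approx(1.0 / 6.0, rel=1e-12)
        for s, side in sub:
            zc = s.mean(axis=0)[2]
            assert (zc > 0.2) == (side > 0)


@pytest.fixture(scope="module")
def split_bar():
    """Bar on [0,2]x[0,1]^2 fully cut at x = 1.06, ends constrained."""
    mesh = make_bar_mesh(nx=9, ny=5, nz=5, pitch=0.25)
    crack = plane_crack(1.06)
    x = mesh.node_coords
    left = np.nonzero(x[:, 0] < 1e-9)[0]
    right = np.nonzero(x[:, 0] > 2 - 1e-9)[0]
    bcs = BoundaryConditionSet()
    bcs.update(left, np.zeros((len(left), 3)))
    bcs.update(right, np.tile([0.5, 0.0, 0.0], (len(right), 1)))
    return mesh, crack, bcs


class TestEnrichedSolve:
    def test_empty_enrichment_reproduces_fem_matrix(self, bar_mesh):
        crack = plane_crack(50.0)
        table = build_enrichment(bar_mesh, crack, HEAVISIDE)
        law = MaterialLaw()
        K_x = xfem_assemble(bar_mesh, law, table)
        K_f = assemble_stiffness(bar_mesh, law)
        assert (K_x != K_f).nnz == 0

    def test_enriched_matrix_symmetric(self, split_bar):
        mesh, crack, _ = split_bar
        table = build_enrichment(mesh, crack, HEAVISIDE)
        K = xfem_assemble(mesh, MaterialLaw(), table)
        assert abs(K - K.T).max() < 1e-9 * abs(K).max()

    def test_split_bar_rigid_halves_and_jump(self, split_bar):
        mesh, crack, bcs = split_bar
        sol = xfem_assemble_solve(mesh, MaterialLaw(), crack, HEAVISIDE, bcs)
        # one-sided limits on the crack plane differ by the prescribed 0.5
        mid = [1.06, 0.5, 0.5]
        up = evaluate_displacement(mid, mesh, sol, crack=crack, side=+1)
        um = evaluate_displacement(mid, mesh, sol, crack=crack, side=-1)
        assert np.allclose(up - um, [0.5, 0, 0], atol=1e-8)
        # each half moves rigidly: zero strain of the effective per-side field
        table = sol.enrichment
        for side, expect in ((-1, 0.0), (1, 0.5)):
            u_eff = sol.u.copy()
            for j, nd in enumerate(table.enriched_nodes):
                g = 1.0 if side > 0 else -1.0
                u_eff[nd] += g * sol.a[j]
            uncut = [t for t in range(mesh.n_tets) if t not in table.cut_tets
                     and table.tet_side[t] == side]
            eps = element_strain(mesh, u_eff)[uncut]
            assert np.abs(eps).max() < 1e-8
            interior = [0.5 + (side > 0), 0.5, 0.5]
            u_i = evaluate_displacement(interior, mesh, sol, crack=crack)
            assert np.allclose(u_i, [expect, 0, 0], atol=1e-8)

    def test_hole_and_heaviside_agree_on_retained_side(self, split_bar):
        mesh, crack, bcs = split_bar
        solH = xfem_assemble_solve(mesh, MaterialLaw(), crack, HEAVISIDE, bcs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # removed-side DOFs are pinned
            solV = xfem_assemble_solve(mesh, MaterialLaw(), crack, HOLE, bcs)
        for pt in ([1.5, 0.5, 0.5], [1.75, 0.25, 0.75], [1.3, 0.8, 0.2]):
            uH = evaluate_displacement(pt, mesh, solH, crack=crack)
            uV = evaluate_displacement(pt, mesh, solV, crack=crack)
            assert np.allclose(uH, uV, atol=1e-7)

    def test_uncut_problem_equals_fem(self, bar_mesh):
        from brainshift_xfem.fem_core import solve_fem
        x = bar_mesh.node_coords
        left = np.nonzero(x[:, 0] < 1e-9)[0]
        right = np.nonzero(x[:, 0] > x[:, 0].max() - 1e-9)[0]
        bcs = BoundaryConditionSet()
        bcs.update(left, np.zeros((len(left), 3)))
        bcs.update(right, np.tile([0.1, 0.0, 0.0], (len(right), 1)))
        sol = xfem_assemble_solve(bar_mesh, MaterialLaw(), plane_crack(50.0), HEAVISIDE, bcs)
        u_fem = solve_fem(bar_mesh, MaterialLaw(), bcs)
        assert np.abs(sol.u - u_fem).max() < 1e-10


class TestEvaluation:
    def test_unenriched_node_value(self, split_bar):
        mesh, crack, bcs = split_bar
        sol = xfem_assemble_solve(mesh, MaterialLaw(), crack, HEAVISIDE, bcs)
        nd = int(np.nonzero(np.abs(mesh.node_coords[:, 0] - 0.25) < 1e-9)[0][0])
        u = evaluate_displacement(mesh.node_coords[nd], mesh, sol, crack=crack)
        assert np.allclose(u, sol.u[nd], atol=1e-12)

    def test_enriched_node_positive_side_limit(self, split_bar):
        mesh, crack, bcs = split_bar
        sol = xfem_assemble_solve(mesh, MaterialLaw(), crack, HEAVISIDE, bcs)
        table = sol.enrichment
        j = 0
        nd = int(table.enriched_nodes[j])
        u = evaluate_displacement(mesh.node_coords[nd], mesh, sol, crack=crack, side=+1)
        assert np.allclose(u, sol.u[nd] + sol.a[j], atol=1e-12)

    def test_jump_matches_enrichment_algebra(self, split_bar):
        """Mid-edge jump equals 2 * sum(phi_i a_i) over enriched nodes (Heaviside)."""
        mesh, crack, bcs = split_bar
        sol = xfem_assemble_solve(mesh, MaterialLaw(), crack, HEAVISIDE, bcs)
        table = sol.enrichment
        from brainshift_xfem.xfem_core import TetLocator
        loc = TetLocator(mesh)
        pt = np.array([1.06, 0.4, 0.6])
        t, lam = loc.locate(pt)
        expect = np.zeros(3)
        for i, nd in enumerate(mesh.tets[t]):
            j = table.enriched_index(int(nd))
            if j is not None:
                expect += 2.0 * lam[i] * sol.a[j]
        up = evaluate_displacement(pt, mesh, sol, crack=crack, side=+1)
        um = evaluate_displacement(pt, mesh, sol, crack=crack, side=-1)
        assert np.allclose(up - um, expect, atol=1e-12)

    def test_outside_point_errors(self, split_bar):
        mesh, crack, bcs = split_bar
        sol = xfem_assemble_solve(mesh, MaterialLaw(), crack, HEAVISIDE, bcs)
        with pytest.raises(ValueError, match="outside"):
            evaluate_displacement([10.0, 10.0, 10.0], mesh, sol, crack=crack)
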