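"""Heaviside/hole-enriched XFEM on tetrahedral meshes.

A resection cavity introduces a displacement discontinuity.  Instead of
remeshing, nodes whose support is fully intersected by the discontinuity
receive three extra (enriched) DOFs ``a_j`` multiplying a discontinuous
function g(x):

    u(x) = sum_i phi_i(x) u_i  +  sum_{j in J} phi_j(x) g(x) a_j

with g either the Heaviside function H(x) = +-1 by the side of the crack,
or the hole function V(x) in {1, 0}, which additionally removes the
negative (resected) side from the stiffness integration so that the
removed tissue has no influence on the retained side.  Enrichment is
unshifted (the interpolation is exactly the expression above), so
prescribed displacements are meaningful only at un-enriched nodes; when a
constrained node is nevertheless enriched, its enriched DOFs are pinned to
zero.

Cut elements are integrated by splitting each tetrahedron along the
linearly interpolated signed side value of its corners (marching-tet
subdivision), which conserves the parent volume to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .core_mesh import MaterialLaw, TetMesh, TriSurface
from .fem_core import (
    BoundaryConditionSet,
    _batched_B,
    _batched_gradients,
    assemble_stiffness,
    shape_gradients,
    solve_fixed_dofs,
    strain_displacement_matrix,
)
from .proximity import SurfaceProximity

HEAVISIDE = "heaviside"
HOLE = "hole"


@dataclass
class CrackSurface:
    """Triangulated discontinuity (resection-cavity boundary).

    Triangle normals must point away from the removed side: the enrichment
    functions are +1 (Heaviside) or 1 (hole) on the positive side
    ``(x - x*) . e_n > 0`` — the retained tissue — and -1 or 0 on the
    removed side.
    """

    surface: TriSurface
    closed: bool = True

    def __post_init__(self) -> None:
        self._query: SurfaceProximity | None = None

    @property
    def query(self) -> SurfaceProximity:
        if self._query is None:
            self._query = SurfaceProximity(self.surface)
        return self._query

    def signed_values(self, points: np.ndarray) -> np.ndarray:
        return self.query.signed_values(points)

    def flipped(self) -> "CrackSurface":
        tris = self.surface.triangles[:, [0, 2, 1]]
        return CrackSurface(TriSurface(self.surface.vertices.copy(), tris), self.closed)


def enrichment_function(
    x: np.ndarray, crack: CrackSurface, kind: str = HEAVISIDE, tol: float | None = None
) -> float:
    """Evaluate H(x) in {+1, -1} or V(x) in {1, 0} at one point.

    Raises ``OnCrackError`` when |(x - x*) . e_n| falls below ``tol``
    (default 1e-6 of the crack's characteristic edge); the caller should
    perturb the point along the crack normal.
    """
    d = float(crack.signed_values(np.asarray(x, dtype=float).reshape(1, 3))[0])
    if tol is None:
        tol = 1e-6 * crack.query.char_edge
    if abs(d) < tol:
        raise OnCrackError(f"point lies on the crack (signed value {d:g})")
    return _g_value(1.0 if d > 0 else -1.0, kind)


class OnCrackError(ValueError):
    """Evaluation point lies on the discontinuity within tolerance."""


def _g_value(side: float, kind: str) -> float:
    if kind == HEAVISIDE:
        return 1.0 if side > 0 else -1.0
    if kind == HOLE:
        return 1.0 if side > 0 else 0.0
    raise ValueError(f"unknown enrichment kind {kind!r}")


# ---------------------------------------------------------------------------
# Cut-element subdivision
# ---------------------------------------------------------------------------

def split_tet_by_levelset(coords: np.ndarray, values: np.ndarray):
    """Split one tet by the zero level of linearly interpolated nodal values.

    Returns a list of ``(subtet_coords (4, 3), side)`` whose volumes sum to
    the parent volume to machine precision.  ``side`` is +1/-1.
    """
    coords = np.asarray(coords, dtype=float).reshape(4, 3)
    d = np.asarray(values, dtype=float).reshape(4).copy()
    d[d == 0] = 1e-300  # zeros counted on the positive side
    pos = d > 0
    npos = int(pos.sum())
    if npos in (0, 4):
        return [(coords.copy(), 1 if npos == 4 else -1)]

    def cut(i: int, j: int) -> np.ndarray:
        t = d[i] / (d[i] - d[j])
        return coords[i] + t * (coords[j] - coords[i])

    idx = np.arange(4)
    if npos in (1, 3):
        # apex on the minority side, prism on the majority side
        apex_side = 1 if npos == 1 else -1
        a = int(idx[pos][0]) if npos == 1 else int(idx[~pos][0])
        others = [int(i) for i in idx if i != a]
        p = [cut(a, o) for o in others]
        sub = [(np.array([coords[a], p[0], p[1], p[2]]), apex_side)]
        b, c, e = (coords[o] for o in others)
        # prism (b, c, e | p0, p1, p2) split into 3 tets
        sub.append((np.array([b, c, e, p[0]]), -apex_side))
        sub.append((np.array([c, e, p[0], p[1]]), -apex_side))
        sub.append((np.array([e, p[0], p[1], p[2]]), -apex_side))
        return sub

    # 2-2 case: two wedges, each split into 3 tets.  All wedge faces are
    # planar (cut quad lies in the cut plane, side quads on tet faces), so
    # the decomposition is exact.
    A, B = (int(i) for i in idx[pos])
    C, E = (int(i) for i in idx[~pos])
    pac, pae = cut(A, C), cut(A, E)
    pbc, pbe = cut(B, C), cut(B, E)
    # Each wedge vertex pairs with the cut points on its own tet edges; the
    # two wedges share the cut-quad diagonal pac-pbe, so they tile exactly.
    sub = []
    for (v0, v1, q00, q01, q10, q11, side) in (
        (coords[A], coords[B], pac, pae, pbc, pbe, 1),
        (coords[C], coords[E], pac, pbc, pae, pbe, -1),
    ):
        # prism with triangle faces (v0, q00, q01) and (v1, q10, q11)
        sub.append((np.array([v0, q00, q01, v1]), side))
        sub.append((np.array([v1, q00, q01, q11]), side))
        sub.append((np.array([v1, q00, q11, q10]), side))
    return sub


def subdivide_cut_tet(tet_coords: np.ndarray, crack: CrackSurface):
    """Subcell quadrature of a tet cut by a crack: list of (subtet, side)."""
    d = crack.signed_values(np.asarray(tet_coords, dtype=float).reshape(4, 3))
    return split_tet_by_levelset(tet_coords, d)


def _tet_volume(coords: np.ndarray) -> float:
    return abs(
        np.dot(coords[1] - coords[0], np.cross(coords[2] - coords[0], coords[3] - coords[0]))
    ) / 6.0


# ---------------------------------------------------------------------------
# Enrichment bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentTable:
    """Per-node DOF ledger for one discontinuity.

    Standard DOFs come first (3 per node, node-major), then 3 enriched DOFs
    per node of the enriched set J.  ``cut_tets`` maps tet index to its
    subcell list; ``tet_side`` holds the side of every uncut tet.
    """

    n_nodes: int
    enriched_nodes: np.ndarray
    kind: str
    node_signs: np.ndarray
    cut_tets: dict[int, list] = field(default_factory=dict)
    tet_side: np.ndarray | None = None
    dropped_nodes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.enriched_nodes = np.asarray(self.enriched_nodes, dtype=np.int64)
        self._enr_index = {int(n): i for i, n in enumerate(self.enriched_nodes)}

    @property
    def n_enriched(self) -> int:
        return len(self.enriched_nodes)

    @property
    def n_standard_dofs(self) -> int:
        return 3 * self.n_nodes

    @property
    def n_enriched_dofs(self) -> int:
        return 3 * self.n_enriched

    @property
    def total_dofs(self) -> int:
        return self.n_standard_dofs + self.n_enriched_dofs

    def dofs_of_node(self, node: int) -> int:
        """Number of DOFs carried by one node (3, or 6 when enriched)."""
        return 6 if int(node) in self._enr_index else 3

    def enriched_index(self, node: int) -> int | None:
        return self._enr_index.get(int(node))

    def enriched_dof_indices(self, node: int) -> np.ndarray:
        i = self._enr_index[int(node)]
        return self.n_standard_dofs + 3 * i + np.arange(3)

    def report(self) -> dict:
        return {
            "n_nodes": int(self.n_nodes),
            "n_enriched_nodes": int(self.n_enriched),
            "standard_dofs": int(self.n_standard_dofs),
            "enriched_dofs": int(self.n_enriched_dofs),
            "total_dofs": int(self.total_dofs),
            "n_cut_tets": len(self.cut_tets),
            "kind": self.kind,
        }


def build_enrichment(
    mesh: TetMesh,
    crack: CrackSurface,
    kind: str = HEAVISIDE,
    min_support_fraction: float = 1e-4,
) -> EnrichmentTable:
    """Identify enriched nodes and subdivide cut elements.

    A node enters J when its support (union of incident tets) is fully
    intersected: both sides of the crack hold a volume fraction of at least
    ``min_support_fraction`` within the support (the standard conditioning
    guard).  A crack entirely outside the mesh yields an empty table, in
    which case the XFEM solve reduces exactly to FEM.
    """
    d = crack.signed_values(mesh.node_coords)
    # Nodes numerically on the crack are counted on the positive side.
    eps = 1e-12 * max(crack.query.char_edge, 1.0)
    d = np.where(np.abs(d) < eps, eps, d)
    signs = np.where(d > 0, 1, -1).astype(np.int8)

    node_sign_per_tet = signs[mesh.tets]
    mixed = np.any(node_sign_per_tet != node_sign_per_tet[:, [0]], axis=1)

    cut_tets: dict[int, list] = {}
    vols = np.abs(mesh.tet_volumes())
    pos_vol = np.zeros(mesh.n_nodes)
    neg_vol = np.zeros(mesh.n_nodes)
    tet_side = node_sign_per_tet[:, 0].astype(np.int8)

    for t in np.nonzero(mixed)[0]:
        coords = mesh.node_coords[mesh.tets[t]]
        sub = split_tet_by_levelset(coords, d[mesh.tets[t]])
        cut_tets[int(t)] = sub
        vpos = sum(_tet_volume(s) for s, side in sub if side > 0)
        vneg = sum(_tet_volume(s) for s, side in sub if side < 0)
        for nd in mesh.tets[t]:
            pos_vol[nd] += vpos
            neg_vol[nd] += vneg

    uncut = ~mixed
    for t in np.nonzero(uncut)[0]:
        target = pos_vol if tet_side[t] > 0 else neg_vol
        for nd in mesh.tets[t]:
            target[nd] += vols[t]

    both = (pos_vol > 0) & (neg_vol > 0)
    total = pos_vol + neg_vol
    frac = np.zeros(mesh.n_nodes)
    frac[both] = np.minimum(pos_vol[both], neg_vol[both]) / total[both]
    enriched = np.nonzero(frac >= min_support_fraction)[0]
    dropped = np.nonzero(both & (frac < min_support_fraction))[0]
    if len(dropped):
        warnings.warn(
            f"{len(dropped)} near-degenerate enriched DOFs eliminated "
            f"(support volume fraction < {min_support_fraction:g})"
        )
    return EnrichmentTable(
        n_nodes=mesh.n_nodes,
        enriched_nodes=enriched,
        kind=kind,
        node_signs=signs,
        cut_tets=cut_tets,
        tet_side=tet_side,
        dropped_nodes=dropped,
    )


# ---------------------------------------------------------------------------
# Enriched assembly and solve
# ---------------------------------------------------------------------------

@dataclass
class XFEMSolution:
    """Standard nodal field plus enriched DOF values for one increment."""

    u: np.ndarray                 # (n_nodes, 3) mm
    a: np.ndarray                 # (n_enriched, 3) mm
    enrichment: EnrichmentTable


def xfem_assemble(mesh: TetMesh, law: MaterialLaw, enrichment: EnrichmentTable) -> sparse.csr_matrix:
    """Sparse symmetric enriched stiffness (3|I| + 3|J| DOFs).

    With an empty enrichment this returns exactly the FEM stiffness.  With
    the hole kind, tets and subcells on the negative (removed) side are
    skipped entirely: the removed material contributes zero stiffness.
    """
    if enrichment.n_enriched == 0 and not enrichment.cut_tets and enrichment.kind != HOLE:
        return assemble_stiffness(mesh, law)

    D = law.hooke_voigt()
    kind = enrichment.kind
    enr_set = set(int(n) for n in enrichment.enriched_nodes)
    cut = enrichment.cut_tets
    tet_side = enrichment.tet_side
    grads, vols = _batched_gradients(mesh)

    touched = np.zeros(mesh.n_tets, dtype=bool)
    for t in cut:
        touched[t] = True
    if enr_set:
        has_enr = np.isin(mesh.tets, enrichment.enriched_nodes).any(axis=1)
        touched |= has_enr

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    data: list[np.ndarray] = []

    # Plain tets: batched standard assembly (skipping removed-side tets for hole).
    plain = ~touched
    if kind == HOLE:
        plain = plain & (tet_side > 0)
    if plain.any():
        Bp = _batched_B(grads[plain])
        Ke = np.einsum("nai,ab,nbj,n->nij", Bp, D, Bp, vols[plain], optimize=True)
        dof = (3 * mesh.tets[plain][:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
        rows.append(np.repeat(dof, 12, axis=1).ravel())
        cols.append(np.tile(dof, (1, 12)).ravel())
        data.append(Ke.ravel())

    # Enriched / cut tets: per-element loop.
    for t in np.nonzero(touched)[0]:
        tet_nodes = mesh.tets[t]
        enr_local = [i for i, nd in enumerate(tet_nodes) if int(nd) in enr_set]
        g = grads[t]
        B_std = strain_displacement_matrix(g)
        dofs = list((3 * tet_nodes[:, None] + np.arange(3)).ravel())
        for i in enr_local:
            dofs.extend(enrichment.enriched_dof_indices(tet_nodes[i]))
        ndof = len(dofs)
        Ke = np.zeros((ndof, ndof))

        if int(t) in cut:
            pieces = [(s, side) for (s, side) in cut[int(t)]]
        else:
            pieces = [(None, int(tet_side[t]))]
        for coords_s, side in pieces:
            if kind == HOLE and side < 0:
                continue
            gval = _g_value(side, kind)
            vol = vols[t] if coords_s is None else _tet_volume(coords_s)
            if vol <= 0:
                continue
            Bf = np.zeros((6, ndof))
            Bf[:, :12] = B_std
            for k, i in enumerate(enr_local):
                Bf[:, 12 + 3 * k: 15 + 3 * k] = gval * B_std[:, 3 * i: 3 * i + 3]
            Ke += vol * Bf.T @ D @ Bf
        dofs = np.asarray(dofs, dtype=np.int64)
        rows.append(np.repeat(dofs, ndof))
        cols.append(np.tile(dofs, ndof))
        data.append(Ke.ravel())

    n = enrichment.total_dofs
    K = sparse.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    return K


def xfem_assemble_solve(
    mesh: TetMesh,
    law: MaterialLaw,
    crack: CrackSurface | None,
    kind: str,
    bcs: BoundaryConditionSet,
    enrichment: EnrichmentTable | None = None,
    rtol: float = 1e-10,
) -> XFEMSolution:
    """Enriched solve with displacement BCs on (preferably uncut) nodes.

    Prescribed nodes that turn out to be enriched keep their prescribed
    standard DOFs and have their enriched DOFs pinned to zero (so the
    prescribed displacement is attained on the node's own side).  DOFs with
    numerically zero diagonal — e.g. nodes whose material was removed by
    the hole function — are pinned to zero with a warning.
    """
    bcs.validate_against(mesh)
    if enrichment is None:
        if crack is None:
            enrichment = EnrichmentTable(
                mesh.n_nodes, np.zeros(0, dtype=np.int64), kind,
                np.ones(mesh.n_nodes, dtype=np.int8),
                tet_side=np.ones(mesh.n_tets, dtype=np.int8),
            )
        else:
            enrichment = build_enrichment(mesh, crack, kind)
    K = xfem_assemble(mesh, law, enrichment)

    nodes = bcs.nodes()
    vals = bcs.values()
    fixed = list((3 * nodes[:, None] + np.arange(3)).ravel())
    fixed_vals = list(vals.ravel())
    n_enr_bc = 0
    for nd in nodes:
        idx = enrichment.enriched_index(int(nd))
        if idx is not None:
            fixed.extend(enrichment.enriched_dof_indices(int(nd)))
            fixed_vals.extend([0.0, 0.0, 0.0])
            n_enr_bc += 1
    if n_enr_bc:
        warnings.warn(
            f"{n_enr_bc} prescribed nodes are enriched; their enriched DOFs are pinned to zero"
        )

    diag = np.asarray(K.diagonal())
    scale = diag.max() if diag.size else 1.0
    dead = np.nonzero(diag <= 1e-12 * scale)[0]
    dead = np.setdiff1d(dead, np.asarray(fixed, dtype=np.int64))
    if len(dead):
        warnings.warn(f"{len(dead)} zero-stiffness DOFs pinned to zero (removed material)")
        fixed.extend(dead.tolist())
        fixed_vals.extend([0.0] * len(dead))

    uflat = solve_fixed_dofs(K, np.asarray(fixed, dtype=np.int64), np.asarray(fixed_vals), rtol)
    ns = enrichment.n_standard_dofs
    return XFEMSolution(
        u=uflat[:ns].reshape(-1, 3),
        a=uflat[ns:].reshape(-1, 3),
        enrichment=enrichment,
    )


# ---------------------------------------------------------------------------
# Field evaluation
# ---------------------------------------------------------------------------

class TetLocator:
    """Point-in-tet location via a k-d tree over tet centroids."""

    def __init__(self, mesh: TetMesh, k: int = 32):
        self.mesh = mesh
        self._tree = cKDTree(mesh.tet_centroids())
        self._k = min(k, mesh.n_tets)

    def locate(self, x: np.ndarray, tol: float = 1e-9):
        """Return (tet index, barycentric coords) or raise for outside points."""
        x = np.asarray(x, dtype=float).reshape(3)
        _, cand = self._tree.query(x, k=self._k)
        cand = np.atleast_1d(cand)
        for t in cand:
            lam = self.barycentric(int(t), x)
            if np.all(lam >= -tol):
                return int(t), lam
        raise ValueError(f"point {x} lies outside the mesh")

    def barycentric(self, t: int, x: np.ndarray) -> np.ndarray:
        c = self.mesh.node_coords[self.mesh.tets[t]]
        M = np.vstack([c.T, np.ones(4)])
        return np.linalg.solve(M, np.append(x, 1.0))


def evaluate_displacement(
    x: np.ndarray,
    mesh: TetMesh,
    solution: XFEMSolution,
    crack: CrackSurface | None = None,
    side: float | None = None,
    locator: TetLocator | None = None,
) -> np.ndarray:
    """Evaluate the enriched interpolation at a point.

    ``side`` forces the crack side (+1/-1) to obtain one-sided limits on the
    discontinuity; otherwise the side comes from the crack geometry (points
    exactly on the crack are perturbed to the positive side).
    """
    enr = solution.enrichment
    loc = locator if locator is not None else TetLocator(mesh)
    t, lam = loc.locate(x)
    nodes = mesh.tets[t]
    u = np.einsum("a,ak->k", lam, solution.u[nodes])
    if enr.n_enriched == 0:
        return u
    enr_local = [(i, enr.enriched_index(int(nd))) for i, nd in enumerate(nodes)]
    enr_local = [(i, j) for i, j in enr_local if j is not None]
    if not enr_local:
        return u
    if side is None:
        if crack is None:
            raise ValueError("crack geometry needed to evaluate the enriched field")
        d = float(crack.signed_values(np.asarray(x, dtype=float).reshape(1, 3))[0])
        side = 1.0 if d >= 0 else -1.0
    g = _g_value(side, enr.kind)
    for i, j in enr_local:
        u = u + lam[i] * g * solution.a[j]
    return u
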