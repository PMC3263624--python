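"""Linear-elastic FEM on tetrahedra with displacement boundary conditions.

The solver works on the *initial* configuration throughout a serial run:
because the formulation is linear, displacement increments solved
independently on the initial mesh superpose to the current configuration
(sigma = C * sum(eps_k)).  The initial stress state is unknown and set to
zero for every solve.

Displacement fields are plain ``(n_nodes, 3)`` float arrays in mm, aligned
with the mesh node list.  DOF ordering is node-major: (ux, uy, uz) of node
0, then node 1, ...
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as sla

from .core_mesh import MaterialLaw, TetMesh


@dataclass
class BoundaryConditionSet:
    """Prescribed displacement increments, node index -> 3-vector (mm)."""

    entries: dict[int, np.ndarray] = field(default_factory=dict)

    def set(self, node: int, disp) -> None:
        self.entries[int(node)] = np.asarray(disp, dtype=float).reshape(3)

    def update(self, nodes, disps) -> None:
        for n, d in zip(np.asarray(nodes, dtype=int), np.asarray(disps, dtype=float)):
            self.set(int(n), d)

    def __len__(self) -> int:
        return len(self.entries)

    def nodes(self) -> np.ndarray:
        return np.fromiter(self.entries.keys(), dtype=np.int64, count=len(self.entries))

    def values(self) -> np.ndarray:
        if not self.entries:
            return np.zeros((0, 3))
        return np.stack([self.entries[int(n)] for n in self.nodes()])

    def validate_against(self, mesh: TetMesh) -> None:
        if len(self.entries) and (self.nodes().min() < 0 or self.nodes().max() >= mesh.n_nodes):
            raise ValueError("boundary condition node index out of range")


def shape_gradients(tet_coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Gradients of the 4 linear nodal shape functions and the tet volume.

    Returns ``(grads, volume)`` with ``grads`` of shape (4, 3); gradients
    are constant over the element (constant-strain tetrahedron).
    """
    x = np.asarray(tet_coords, dtype=float)
    J = x[1:] - x[0]  # rows: edge vectors
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    if vol <= 0:
        raise ValueError(f"degenerate or inverted tetrahedron (volume {vol:g})")
    dN = np.linalg.inv(J).T  # gradients of N1..N3 w.r.t. x
    grads = np.vstack([-dN.sum(axis=0), dN])
    return grads, vol


def strain_displacement_matrix(grads: np.ndarray) -> np.ndarray:
    """6x(3n) Voigt B-matrix (xx, yy, zz, yz, xz, xy; engineering shear)."""
    n = len(grads)
    B = np.zeros((6, 3 * n))
    for a in range(n):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c + 1] = gz
        B[3, c + 2] = gy
        B[4, c] = gz
        B[4, c + 2] = gx
        B[5, c] = gy
        B[5, c + 1] = gx
    return B


def element_stiffness(tet_coords: np.ndarray, law: MaterialLaw) -> np.ndarray:
    """12x12 stiffness of a constant-strain tetrahedron, K = V * B^T D B.

    Symmetric positive-semidefinite with exactly six zero eigenvalues (the
    rigid-body modes).
    """
    grads, vol = shape_gradients(tet_coords)
    B = strain_displacement_matrix(grads)
    return vol * B.T @ law.hooke_voigt() @ B


def _batched_gradients(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients (n_tets, 4, 3) and volumes for every tet."""
    x = mesh.node_coords[mesh.tets]
    J = x[:, 1:] - x[:, :1]
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        bad = int(np.argmin(detJ))
        raise ValueError(f"degenerate or inverted tetrahedron at index {bad}")
    dN = np.transpose(np.linalg.inv(J), (0, 2, 1))
    grads = np.concatenate([-dN.sum(axis=1, keepdims=True), dN], axis=1)
    return grads, detJ / 6.0


def _batched_B(grads: np.ndarray) -> np.ndarray:
    """(n, 6, 12) Voigt B-matrices from batched gradients (n, 4, 3)."""
    n = len(grads)
    B = np.zeros((n, 6, 12))
    gx, gy, gz = grads[..., 0], grads[..., 1], grads[..., 2]
    for a in range(4):
        c = 3 * a
        B[:, 0, c] = gx[:, a]
        B[:, 1, c + 1] = gy[:, a]
        B[:, 2, c + 2] = gz[:, a]
        B[:, 3, c + 1] = gz[:, a]
        B[:, 3, c + 2] = gy[:, a]
        B[:, 4, c] = gz[:, a]
        B[:, 4, c + 2] = gx[:, a]
        B[:, 5, c] = gy[:, a]
        B[:, 5, c + 1] = gx[:, a]
    return B


def assemble_stiffness(mesh: TetMesh, law: MaterialLaw) -> sparse.csr_matrix:
    """Sparse symmetric global stiffness, 3*n_nodes DOFs, node-major ordering."""
    grads, vols = _batched_gradients(mesh)
    B = _batched_B(grads)
    D = law.hooke_voigt()
    Ke = np.einsum("nai,ab,nbj,n->nij", B, D, B, vols, optimize=True)
    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def solve_fixed_dofs(
    K: sparse.spmatrix,
    fixed: np.ndarray,
    fixed_values: np.ndarray,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Solve K u = 0 with an arbitrary set of DOFs prescribed.

    Symmetric row/column elimination: the free block ``K_ff u_f = -K_fc u_c``
    is factorized directly (sparse LU), with a CG fallback at tolerance
    ``rtol`` if the factorization fails.  Returns the flat DOF vector.
    """
    n = K.shape[0]
    fixed = np.asarray(fixed, dtype=np.int64)
    u = np.zeros(n)
    u[fixed] = np.asarray(fixed_values, dtype=float).ravel()
    free = np.setdiff1d(np.arange(n), fixed, assume_unique=False)
    if len(free) == 0:
        return u

    K = K.tocsr()
    Kff = K[free][:, free]
    rhs = -K[free][:, fixed] @ u[fixed]
    try:
        lu = sla.splu(Kff.tocsc())
        uf = lu.solve(rhs)
        if not np.all(np.isfinite(uf)):
            raise RuntimeError("singular system")
    except (RuntimeError, ValueError) as exc:
        warnings.warn(f"sparse LU failed ({exc}); falling back to CG")
        uf, info = sla.cg(Kff, rhs, rtol=rtol, maxiter=20000)
        if info != 0:
            raise RuntimeError("singular or ill-conditioned system: CG did not converge")
    u[free] = uf

    res = np.linalg.norm(Kff @ uf - rhs)
    ref = np.linalg.norm(rhs)
    if ref > 0 and res / ref > 1e-6:
        warnings.warn(f"large relative residual {res / ref:.2e} in Dirichlet solve")
    return u


def solve_dirichlet(
    K: sparse.spmatrix,
    bcs: BoundaryConditionSet,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Solve K u = 0 subject to prescribed nodal displacements.

    Raises if the constraints cannot remove the rigid-body modes.
    """
    n = K.shape[0]
    if n % 3:
        raise ValueError("system size must be a multiple of 3")
    if len(bcs) == 0:
        raise ValueError("floating structure: no displacement constraints given")
    nodes = bcs.nodes()
    vals = bcs.values()
    if len(np.unique(nodes)) < 3:
        raise ValueError("floating structure: at least 3 constrained nodes required")

    fixed = (3 * nodes[:, None] + np.arange(3)).ravel()
    u = solve_fixed_dofs(K, fixed, vals.ravel(), rtol=rtol)
    return u.reshape(-1, 3)


def solve_fem(mesh: TetMesh, law: MaterialLaw, bcs: BoundaryConditionSet) -> np.ndarray:
    """Assemble and solve in one step; returns an (n_nodes, 3) displacement field."""
    bcs.validate_against(mesh)
    return solve_dirichlet(assemble_stiffness(mesh, law), bcs)


def element_strain(mesh: TetMesh, field: np.ndarray) -> np.ndarray:
    """Per-tet constant small-strain tensors eps = sym(grad u), shape (n_tets, 3, 3)."""
    field = np.asarray(field, dtype=float)
    if field.shape != (mesh.n_nodes, 3):
        raise ValueError("displacement field not aligned with mesh nodes")
    grads, _ = _batched_gradients(mesh)
    ue = field[mesh.tets]  # (n, 4, 3)
    gradu = np.einsum("nak,nai->nki", ue, grads)  # du_k/dx_i
    return 0.5 * (gradu + np.transpose(gradu, (0, 2, 1)))


def element_stress(mesh: TetMesh, field: np.ndarray, law: MaterialLaw) -> np.ndarray:
    """Per-tet stress tensors sigma = C eps (Pa, for displacements in mm)."""
    eps = element_strain(mesh, field)
    D = law.hooke_voigt()
    voigt = np.stack(
        [eps[:, 0, 0], eps[:, 1, 1], eps[:, 2, 2],
         2 * eps[:, 1, 2], 2 * eps[:, 0, 2], 2 * eps[:, 0, 1]], axis=1)
    s = voigt @ D.T
    sig = np.zeros_like(eps)
    sig[:, 0, 0], sig[:, 1, 1], sig[:, 2, 2] = s[:, 0], s[:, 1], s[:, 2]
    sig[:, 1, 2] = sig[:, 2, 1] = s[:, 3]
    sig[:, 0, 2] = sig[:, 2, 0] = s[:, 4]
    sig[:, 0, 1] = sig[:, 1, 0] = s[:, 5]
    return sig


def accumulate_increments(fields: list[np.ndarray]) -> np.ndarray:
    """Sum of displacement increments (all aligned with the initial mesh)."""
    if not fields:
        raise ValueError("no increments to accumulate")
    shapes = {np.asarray(f).shape for f in fields}
    if len(shapes) != 1:
        raise ValueError(f"mismatched increment shapes: {shapes}")
    total = np.zeros_like(np.asarray(fields[0], dtype=float))
    for f in fields:
        total += np.asarray(f, dtype=float)
    return total
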