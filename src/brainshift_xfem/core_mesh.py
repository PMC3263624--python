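"""Image and mesh domain types for the serial biomechanical image-update pipeline.

The biomechanical model is a single tetrahedral mesh of the whole-brain
region (healthy brain plus tumor), built once from the first intraoperative
image and never remeshed.  The healthy/tumor interface is conforming by
construction: every tetrahedron carries exactly one region tag, so the
interface coincides with tetrahedron facets and interface nodes are shared
between the two regions.

Coordinate convention: voxel indices are 0-based, world coordinates are
voxel centers, ``world = origin + index * spacing`` (axis-aligned grids,
millimetres throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage

# Canonical label ids. A label volume may use a different legend; these are
# the defaults produced by the phantom generator.
BACKGROUND = 0
HEALTHY = 1
TUMOR = 2
RESECTED = 3

DEFAULT_LEGEND = {
    BACKGROUND: "background",
    HEALTHY: "healthy_brain",
    TUMOR: "tumor",
    RESECTED: "resected",
}


@dataclass
class ScalarImage3D:
    """A 3-D grayscale volume on an axis-aligned grid (world mm)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel-center indices (may be fractional)."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points."""
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def grid_matches(self, other: "ScalarImage3D | LabelImage3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "ScalarImage3D":
        return ScalarImage3D(self.voxels.copy(), self.spacing, self.origin)


@dataclass
class LabelImage3D:
    """Integer segmentation on the same grid as its paired grayscale image.

    ``legend`` maps label id -> region name among ``background``,
    ``healthy_brain``, ``tumor``, ``resected``.  The whole-brain region is
    healthy_brain | tumor (resected cavities are no longer brain tissue).
    """

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 3-D integer array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    _KNOWN_REGIONS = {"background", "healthy_brain", "tumor", "resected", "whole_brain"}

    def _ids_for(self, region: str) -> list[int]:
        if region == "whole_brain":
            names = {"healthy_brain", "tumor"}
        else:
            names = {region}
        ids = [i for i, n in self.legend.items() if n in names]
        if not ids and region not in self._KNOWN_REGIONS and region not in self.legend.values():
            raise KeyError(f"unknown region {region!r}")
        return ids

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask of a named region ('whole_brain' = healthy | tumor)."""
        ids = self._ids_for(region)
        return np.isin(self.labels, ids)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class MaterialLaw:
    """Isotropic linear-elastic constitutive law (Hooke tensor in Voigt form).

    Defaults are the soft-tissue values used for the brain model: Young
    modulus 3000 Pa, Poisson ratio 0.45.  With pure displacement boundary
    conditions the solution is independent of E.
    """

    E: float = 3000.0
    nu: float = 0.45

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young modulus must be positive")
        if not (0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")

    def hooke_voigt(self) -> np.ndarray:
        """6x6 stiffness in Voigt order (xx, yy, zz, yz, xz, xy), engineering shear."""
        E, nu = self.E, self.nu
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.diag_indices(3)] = lam + 2 * mu
        D[3, 3] = D[4, 4] = D[5, 5] = mu
        return D


@dataclass
class TriSurface:
    """Triangulated surface in world mm, optionally with per-vertex normals."""

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_normals(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]), axis=1
        )

    def compute_vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex normals, unit length; stored on the surface."""
        v = self.vertices
        t = self.triangles
        fn = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])  # area-weighted
        vn = np.zeros_like(v)
        for k in range(3):
            np.add.at(vn, t[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        self.vertex_normals = vn / norm
        return self.vertex_normals

    def edges(self) -> np.ndarray:
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        return np.sort(e, axis=1)

    def is_closed(self) -> bool:
        """Every undirected edge borders exactly two triangles."""
        e = self.edges()
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(len(e)) and bool(np.all(counts == 2))

    def euler_characteristic(self) -> int:
        nV = len(np.unique(self.triangles))
        nE = len(np.unique(self.edges(), axis=0))
        nF = len(self.triangles)
        return nV - nE + nF

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def copy(self) -> "TriSurface":
        return TriSurface(
            self.vertices.copy(),
            self.triangles.copy(),
            None if self.vertex_normals is None else self.vertex_normals.copy(),
        )


# Tags used on tetrahedra.
TAG_HEALTHY = 1
TAG_TUMOR = 2
TAG_NAMES = {TAG_HEALTHY: "healthy_brain", TAG_TUMOR: "tumor"}


@dataclass
class TetMesh:
    """Tetrahedral mesh of the whole-brain region (the biomechanical model).

    ``region_tag`` holds one tag per tetrahedron (healthy_brain or tumor).
    The node coordinates are the *initial* configuration; the serial pipeline
    never rewrites them, deformed states are carried as displacement fields.
    """

    node_coords: np.ndarray
    tets: np.ndarray
    region_tag: np.ndarray

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.region_tag = np.asarray(self.region_tag, dtype=np.int32).reshape(-1)
        if len(self.region_tag) != len(self.tets):
            raise ValueError("one region tag per tetrahedron required")
        if self.tets.size and self.tets.max() >= len(self.node_coords):
            raise ValueError("tet node indices out of range")

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes; positive for correctly oriented tets."""
        x = self.node_coords[self.tets]
        return np.einsum(
            "ij,ij->i",
            x[:, 1] - x[:, 0],
            np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]),
        ) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.node_coords[self.tets].mean(axis=1)

    def node_supports(self) -> list[np.ndarray]:
        """For each node, the indices of incident tets (its support)."""
        order = np.argsort(self.tets.ravel(), kind="stable")
        tet_of = np.repeat(np.arange(self.n_tets), 4)[order]
        nodes_sorted = self.tets.ravel()[order]
        bounds = np.searchsorted(nodes_sorted, np.arange(self.n_nodes + 1))
        return [tet_of[bounds[i]: bounds[i + 1]] for i in range(self.n_nodes)]

    def validate(self, tol: float = 1e-12) -> None:
        vols = self.tet_volumes()
        if np.any(vols <= tol):
            bad = int(np.argmin(vols))
            raise ValueError(f"tet {bad} is degenerate or inverted (volume {vols[bad]:g})")


# ---------------------------------------------------------------------------
# Lattice tetrahedralization
# ---------------------------------------------------------------------------

# Kuhn decomposition of the unit cube into 6 tets sharing the 000-111
# diagonal.  Corner bit order: (bx, by, bz) -> index bx + 2*by + 4*bz.
_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _kuhn_tets() -> np.ndarray:
    tets = []
    for perm in _KUHN_PERMS:
        bits = np.zeros(3, dtype=int)
        verts = [0]
        for ax in perm:
            bits[ax] = 1
            verts.append(int(bits[0] + 2 * bits[1] + 4 * bits[2]))
        tets.append(verts)
    return np.asarray(tets, dtype=np.int64)


_KUHN = _kuhn_tets()


def tetrahedralize_labeled_grid(labels: LabelImage3D, target_edge: float) -> TetMesh:
    """Mesh the whole-brain region of a label volume into tetrahedra.

    The voxel lattice is coarsened by ``round(target_edge / spacing)`` per
    axis; each retained hexahedral cell is split into 6 Kuhn tetrahedra with
    a translation-invariant diagonal, which makes the decomposition
    conforming across cells and deterministic.  A cell is retained when the
    majority (>= 4 of 8) of its corner voxels are brain (healthy or tumor);
    each tet is tagged by the label of the voxel containing its centroid.

    Raises ``ValueError`` for an empty/disconnected brain region or a
    target edge below the voxel spacing.
    """
    spacing = np.asarray(labels.spacing)
    if target_edge < min(labels.spacing):
        raise ValueError("target_edge must be at least the voxel spacing")
    brain = labels.region_mask("whole_brain")
    if not brain.any():
        raise ValueError("whole-brain region is empty")
    n_comp = ndimage.label(brain)[1]
    if n_comp != 1:
        raise ValueError(f"whole-brain region must be 6-connected (found {n_comp} components)")

    shape = np.asarray(labels.shape)
    f = np.maximum(1, np.round(target_edge / spacing).astype(int))
    # Coarse lattice of voxel indices (clipped so the last layer sits on the grid).
    axes = [np.unique(np.minimum(np.arange(0, shape[a] + f[a], f[a]), shape[a] - 1))
            for a in range(3)]
    nax = [len(ax) for ax in axes]

    # Corner brain-ness on the coarse lattice.
    gi, gj, gk = np.meshgrid(axes[0], axes[1], axes[2], indexing="ij")
    corner_brain = brain[gi, gj, gk]

    # Cell inclusion: majority of the 8 corners inside the brain.
    c = corner_brain
    count = (
        c[:-1, :-1, :-1].astype(int) + c[1:, :-1, :-1] + c[:-1, 1:, :-1] + c[:-1, :-1, 1:]
        + c[1:, 1:, :-1] + c[1:, :-1, 1:] + c[:-1, 1:, 1:] + c[1:, 1:, 1:]
    )
    keep = count >= 4
    if not keep.any():
        raise ValueError("no lattice cell has a brain-majority corner set")

    ci, cj, ck = np.nonzero(keep)
    # Corner lattice ids for each kept cell, bit order (bx, by, bz).
    def corner_id(di: int, dj: int, dk: int) -> np.ndarray:
        return ((ci + di) * nax[1] + (cj + dj)) * nax[2] + (ck + dk)

    corners = np.stack(
        [corner_id(b & 1, (b >> 1) & 1, (b >> 2) & 1) for b in range(8)], axis=1
    )  # (n_cells, 8)

    used = np.unique(corners)
    remap = np.full(nax[0] * nax[1] * nax[2], -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    li, lj, lk = np.unravel_index(used, nax)
    node_idx = np.stack([axes[0][li], axes[1][lj], axes[2][lk]], axis=1)
    node_coords = labels.voxel_to_world(node_idx)

    cell_nodes = remap[corners]  # (n_cells, 8)
    tets = cell_nodes[:, _KUHN].reshape(-1, 4)  # (6*n_cells, 4)

    mesh = TetMesh(node_coords, tets, np.ones(len(tets), dtype=np.int32))
    # Fix orientation (Kuhn tets alternate handedness depending on permutation parity).
    vols = mesh.tet_volumes()
    flip = vols < 0
    mesh.tets[flip] = mesh.tets[flip][:, [0, 1, 3, 2]]

    # Tag by centroid voxel label; non-brain centroids fall back to the
    # majority brain label among the cell corners.
    cent = mesh.tet_centroids()
    cidx = np.rint(labels.world_to_voxel(cent)).astype(int)
    cidx = np.clip(cidx, 0, shape - 1)
    lab = labels.labels[cidx[:, 0], cidx[:, 1], cidx[:, 2]]
    tumor_ids = [i for i, n in labels.legend.items() if n == "tumor"]
    healthy_ids = [i for i, n in labels.legend.items() if n == "healthy_brain"]
    tag = np.where(np.isin(lab, tumor_ids), TAG_TUMOR, TAG_HEALTHY).astype(np.int32)
    mesh.region_tag = tag

    mesh = _largest_connected_component(mesh)
    mesh.validate()
    return mesh


def _largest_connected_component(mesh: TetMesh) -> TetMesh:
    """Drop stray cells so the mesh is a single node-connected component."""
    parent = np.arange(mesh.n_nodes)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for tet in mesh.tets:
        r = find(tet[0])
        for v in tet[1:]:
            rv = find(v)
            if rv != r:
                parent[rv] = r
    roots = np.array([find(i) for i in range(mesh.n_nodes)])
    vals, counts = np.unique(roots[mesh.tets[:, 0]], return_counts=True)
    main = vals[np.argmax(counts)]
    keep_tet = roots[mesh.tets[:, 0]] == main
    if keep_tet.all():
        return mesh
    tets = mesh.tets[keep_tet]
    tags = mesh.region_tag[keep_tet]
    used = np.unique(tets)
    remap = np.full(mesh.n_nodes, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TetMesh(mesh.node_coords[used], remap[tets], tags)


# Faces of a tet opposite each vertex, ordered so the outward normal of
# face k points away from vertex k for a positively oriented tet.
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def extract_boundary_surface(mesh: TetMesh, region: str = "all") -> TriSurface:
    """Outward-oriented boundary triangles of a tagged sub-region (or the whole mesh).

    A triangle is on the boundary when it belongs to exactly one tetrahedron
    of the selected region.  Vertex indices of the returned surface refer to
    positions copied out of the mesh; ``boundary_node_ids`` on the result
    maps surface vertices back to mesh node indices.
    """
    if region == "all":
        sel = np.ones(mesh.n_tets, dtype=bool)
    elif region == "healthy_brain":
        sel = mesh.region_tag == TAG_HEALTHY
    elif region == "tumor":
        sel = mesh.region_tag == TAG_TUMOR
    else:
        raise KeyError(f"unknown region tag {region!r}")
    tets = mesh.tets[sel]
    if len(tets) == 0:
        raise ValueError(f"region {region!r} contains no tetrahedra")

    faces = tets[:, _TET_FACES]  # (n, 4, 3) oriented outward per tet
    flat = faces.reshape(-1, 3)
    key = np.sort(flat, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inv] == 1
    tris = flat[boundary]

    used = np.unique(tris)
    remap = np.full(mesh.n_nodes, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    surf = TriSurface(mesh.node_coords[used], remap[tris])
    surf.boundary_node_ids = used  # type: ignore[attr-defined]
    surf.compute_vertex_normals()
    return surf


def laplacian_smooth_surface(surface: TriSurface, iterations: int, lam: float = 0.5) -> TriSurface:
    """Umbrella-operator smoothing: each vertex moves toward its 1-ring mean.

    Connectivity is unchanged.  ``lam`` in (0, 1) is the per-iteration step;
    repeated smoothing of a closed surface behaves like mean-curvature flow
    (it shrinks).  Raises on isolated vertices.
    """
    if not (0 < lam < 1):
        raise ValueError("lambda must lie in (0, 1)")
    out = surface.copy()
    n = out.n_vertices
    e = np.vstack([out.triangles[:, [0, 1]], out.triangles[:, [1, 2]], out.triangles[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    deg = np.zeros(n)
    np.add.at(deg, e[:, 0], 1)
    np.add.at(deg, e[:, 1], 1)
    if np.any(deg == 0):
        raise ValueError("surface has isolated vertices")
    for _ in range(iterations):
        acc = np.zeros_like(out.vertices)
        np.add.at(acc, e[:, 0], out.vertices[e[:, 1]])
        np.add.at(acc, e[:, 1], out.vertices[e[:, 0]])
        out.vertices += lam * (acc / deg[:, None] - out.vertices)
    if out.vertex_normals is not None:
        out.compute_vertex_normals()
    return out
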