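"""Surface-landmark displacement estimation between successive images.

The landmarks driving the biomechanical model are the region boundary
surfaces themselves (whole-brain and healthy-brain boundaries).  A
deformable (active) surface initialized from the model boundary is pulled
onto the target image's region boundary by gradient descent on a distance
map, after an optional local rigid ICP pre-alignment of the tumor-facing
patch; per-vertex displacements are then smoothed by an inverse-distance
k-nearest-neighbor average and transferred onto the biomechanical model's
boundary nodes as displacement boundary conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_mesh import LabelImage3D, TetMesh, TriSurface
from .fem_core import BoundaryConditionSet
from .proximity import SurfaceProximity
from .rigid_registration import RigidTransform, fit_landmark_transform


@dataclass
class DistanceMap:
    """Unsigned Euclidean distance (mm) to a region boundary, on an image grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the distance at world points (mm)."""
        idx = self.world_to_voxel(np.atleast_2d(points)).T
        return ndimage.map_coordinates(self.values, idx, order=1, mode="nearest")

    def sample_gradient(self, points: np.ndarray) -> np.ndarray:
        """Central-difference world-space gradient, trilinearly interpolated."""
        if not hasattr(self, "_grad"):
            self._grad = np.stack(np.gradient(self.values, *self.spacing), axis=-1)
        idx = self.world_to_voxel(np.atleast_2d(points)).T
        return np.stack(
            [ndimage.map_coordinates(self._grad[..., k], idx, order=1, mode="nearest")
             for k in range(3)], axis=-1,
        )


def compute_distance_map(region: LabelImage3D, name: str) -> DistanceMap:
    """Exact Euclidean distance transform of a region's boundary voxel set.

    The boundary is the set of region voxels with at least one
    6-neighbor outside the region; spacing anisotropy is respected.
    """
    mask = region.region_mask(name)
    if not mask.any():
        raise ValueError(f"region {name!r} is empty")
    interior = ndimage.binary_erosion(mask)
    boundary = mask & ~interior
    dist = ndimage.distance_transform_edt(~boundary, sampling=region.spacing)
    return DistanceMap(dist, region.spacing, region.origin)


def active_surface_evolve(
    init: TriSurface,
    target: DistanceMap,
    step: float = 0.3,
    alpha_internal: float = 0.2,
    max_iters: int = 200,
    tol: float = 1e-3,
) -> TriSurface:
    """Evolve a surface onto the zero set of a distance map.

    Each vertex moves by ``step * (-D * grad D + alpha_internal * umbrella)``:
    the external force is a damped descent on D^2/2 (it vanishes smoothly on
    the boundary instead of oscillating across the unsigned-distance kink),
    the internal force is uniform Laplacian regularization.  ``step`` is
    dimensionless; iteration stops when the mean vertex motion falls below
    ``tol`` (mm).  Connectivity is unchanged.  Vertices that would leave the
    grid are clamped with a warning.
    """
    out = init.copy()
    n = out.n_vertices
    tris = out.triangles
    e = np.unique(np.sort(np.vstack(
        [tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]), axis=1), axis=0)
    deg = np.zeros(n)
    np.add.at(deg, e[:, 0], 1)
    np.add.at(deg, e[:, 1], 1)
    deg[deg == 0] = 1.0

    lo = np.asarray(target.origin)
    hi = lo + (np.asarray(target.values.shape) - 1) * np.asarray(target.spacing)
    clamped = False
    motion = np.inf
    for _ in range(max_iters):
        D = target.sample(out.vertices)
        G = target.sample_gradient(out.vertices)
        umb = np.zeros_like(out.vertices)
        np.add.at(umb, e[:, 0], out.vertices[e[:, 1]])
        np.add.at(umb, e[:, 1], out.vertices[e[:, 0]])
        umb = umb / deg[:, None] - out.vertices
        delta = step * (-D[:, None] * G + alpha_internal * umb)
        out.vertices += delta
        low = out.vertices < lo
        high = out.vertices > hi
        if low.any() or high.any():
            clamped = True
            np.clip(out.vertices, lo, hi, out=out.vertices)
        motion = float(np.linalg.norm(delta, axis=1).mean())
        if motion < tol:
            break
    else:
        warnings.warn(f"active surface did not converge (mean motion {motion:.3g} mm)")
    if clamped:
        warnings.warn("active-surface vertices clamped to the image grid")
    if out.vertex_normals is not None:
        out.compute_vertex_normals()
    return out


def local_rigid_icp_prealign(
    source_patch: TriSurface,
    target: TriSurface,
    max_iters: int = 50,
    tol: float = 1e-6,
) -> RigidTransform:
    """Rigid iterative-closest-point alignment of a surface patch to a target.

    Alternates closest-point matching against the target vertices with the
    closed-form rigid landmark fit until the RMS residual change drops
    below ``tol`` mm.  The RMS is non-increasing across iterations.
    """
    src = source_patch.vertices
    if len(src) < 3:
        raise ValueError("degenerate patch: fewer than 3 vertices")
    tree = cKDTree(target.vertices)
    # centroid-difference initialization avoids the stall of closest-point
    # matching on largely featureless (convex) shapes at large offsets
    transform = RigidTransform(
        translation=target.vertices.mean(axis=0) - src.mean(axis=0)
    )
    prev_rms = np.inf
    for _ in range(max_iters):
        moved = transform.apply(src)
        d, idx = tree.query(moved)
        rms = float(np.sqrt((d ** 2).mean()))
        if prev_rms - rms < tol:
            break
        prev_rms = rms
        transform = fit_landmark_transform(src, target.vertices[idx], allow_scale=False)
    return transform


def smooth_displacement_knn(
    disp: np.ndarray, surface: TriSurface, n_neighbors: int = 8
) -> np.ndarray:
    """Inverse-distance-weighted average over each vertex and its N nearest vertices.

    N defaults to 8 (the pipeline uses five to ten neighbors depending on the
    deformation).  Weights are ``1 / (d + dbar/2)`` with ``dbar`` the mean
    neighbor distance of the vertex, so the vertex itself gets a finite
    weight and a constant field is left unchanged.
    """
    disp = np.asarray(disp, dtype=float).reshape(-1, 3)
    if len(disp) != surface.n_vertices:
        raise ValueError("displacement length must match vertex count")
    if not (1 <= n_neighbors < surface.n_vertices):
        raise ValueError("neighbor count out of range")
    tree = cKDTree(surface.vertices)
    d, idx = tree.query(surface.vertices, k=n_neighbors + 1)  # first hit is self
    dbar = d[:, 1:].mean(axis=1, keepdims=True)
    dbar[dbar == 0] = 1.0
    w = 1.0 / (d + dbar / 2.0)
    w /= w.sum(axis=1, keepdims=True)
    return np.einsum("nk,nkj->nj", w, disp[idx])


def transfer_to_mesh_boundary(
    disp: np.ndarray,
    tracked: TriSurface,
    mesh: TetMesh,
    boundary_node_ids: np.ndarray,
    node_positions: np.ndarray | None = None,
    max_gap: float | None = None,
) -> BoundaryConditionSet:
    """Interpolate a tracked surface's displacements onto mesh boundary nodes.

    Each selected node (at ``node_positions`` if given, e.g. the deformed
    configuration; the initial coordinates otherwise) takes the
    barycentric interpolation of the per-vertex displacements at its closest
    point on the tracked surface.  ``max_gap`` (mm) rejects nodes farther
    than that from the surface.
    """
    disp = np.asarray(disp, dtype=float).reshape(-1, 3)
    if len(disp) != tracked.n_vertices:
        raise ValueError("displacement length must match tracked surface vertices")
    ids = np.asarray(boundary_node_ids, dtype=np.int64)
    pos = mesh.node_coords[ids] if node_positions is None else np.asarray(node_positions)
    prox = SurfaceProximity(tracked)
    _, dist, tri_idx, bary = prox.closest(pos)
    if max_gap is not None and np.any(dist > max_gap):
        bad = ids[dist > max_gap]
        raise ValueError(
            f"{len(bad)} mesh boundary nodes are farther than {max_gap} mm from the "
            f"tracked surface (worst {dist.max():.2f} mm); first offenders: {bad[:10].tolist()}"
        )
    tri = tracked.triangles[tri_idx]
    vals = np.einsum("nk,nkj->nj", bary, disp[tri])
    bcs = BoundaryConditionSet()
    bcs.update(ids, vals)
    return bcs
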