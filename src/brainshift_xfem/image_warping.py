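"""Carry mesh displacement fields onto the voxel grid and warp images.

The warp is a forward splat: every source voxel is displaced as a rigid
box and deposited onto the output grid, each output voxel taking the
overlap-ratio-weighted mean of the contributing source values.  For a pure
box translation the overlap weights factor per axis, so the splat reduces
to trilinear weight distribution over the (at most) eight covered output
voxels.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .core_mesh import LabelImage3D, ScalarImage3D, TetMesh

BACKGROUND_VALUE = 0.0


def mesh_displacement_to_voxel_field(
    mesh: TetMesh,
    field: np.ndarray,
    grid: ScalarImage3D,
    node_positions: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a nodal displacement field to a dense voxel field (mm).

    Every voxel center inside a tet receives the barycentric interpolation
    of the nodal displacements; outside voxels are zero and flagged.  Pass
    ``node_positions`` to evaluate the mesh in a deformed configuration
    (field values still per node).  Returns ``(field (nx,ny,nz,3), inside)``.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != (mesh.n_nodes, 3):
        raise ValueError("field not aligned with mesh nodes")
    coords = mesh.node_coords if node_positions is None else np.asarray(node_positions)

    shape = grid.shape
    out = np.zeros(shape + (3,))
    inside = np.zeros(shape, dtype=bool)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)

    x = coords[mesh.tets]  # (M, 4, 3)
    # Per-tet barycentric solve prepared as inverse matrices.
    T = np.transpose(x[:, 1:] - x[:, :1], (0, 2, 1))  # columns are edges
    Tinv = np.linalg.inv(T)

    lo = np.floor((x.min(axis=1) - origin) / spacing).astype(int)
    hi = np.ceil((x.max(axis=1) - origin) / spacing).astype(int)
    lo = np.clip(lo, 0, np.asarray(shape) - 1)
    hi = np.clip(hi, 0, np.asarray(shape) - 1)

    for t in range(mesh.n_tets):
        sl = tuple(slice(lo[t, a], hi[t, a] + 1) for a in range(3))
        ii, jj, kk = np.meshgrid(
            *[np.arange(lo[t, a], hi[t, a] + 1) for a in range(3)], indexing="ij"
        )
        pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * spacing + origin
        lam123 = (pts - x[t, 0]) @ Tinv[t].T
        lam = np.column_stack([1.0 - lam123.sum(axis=1), lam123])
        ok = np.all(lam >= -1e-9, axis=1)
        if not ok.any():
            continue
        block_shape = tuple(hi[t] + 1 - lo[t])
        block_inside = inside[sl].reshape(-1)
        write = ok & ~block_inside  # first tet wins on shared facets
        if write.any():
            vals = lam[write] @ field[mesh.tets[t]]
            block_out = out[sl].reshape(-1, 3)
            block_out[write] = vals
            out[sl] = block_out.reshape(block_shape + (3,))
        inside[sl] = (block_inside | ok).reshape(block_shape)
    return out, inside


def forward_warp_overlap_weighted(
    image: ScalarImage3D,
    voxel_field: np.ndarray,
    background: float = BACKGROUND_VALUE,
    fill_holes_within: np.ndarray | None = None,
) -> ScalarImage3D:
    """Forward-warp an image by a dense per-voxel displacement field (mm).

    Each source voxel box is translated by its displacement and splatted
    with per-axis overlap weights; output voxels average their contributions
    by total overlap.  Voxels with zero coverage take ``background`` unless
    they fall inside ``fill_holes_within``, in which case they copy the
    nearest covered voxel's value (logged).
    """
    if voxel_field.shape != image.shape + (3,):
        raise ValueError("voxel field grid does not match image")
    if not np.all(np.isfinite(voxel_field)):
        raise ValueError("non-finite displacements in voxel field")
    shape = np.asarray(image.shape)
    spacing = np.asarray(image.spacing)

    idx = np.indices(image.shape).reshape(3, -1).T.astype(float)
    dest = idx + voxel_field.reshape(-1, 3) / spacing  # fractional voxel position
    base = np.floor(dest).astype(np.int64)
    frac = dest - base

    vals = image.voxels.reshape(-1)
    acc = np.zeros(image.shape, dtype=float).reshape(-1)
    wsum = np.zeros(image.shape, dtype=float).reshape(-1)
    strides = np.array([shape[1] * shape[2], shape[2], 1])

    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
        tgt = base + off
        okm = np.all((tgt >= 0) & (tgt < shape), axis=1) & (w > 0)
        flat = tgt[okm] @ strides
        np.add.at(acc, flat, w[okm] * vals[okm])
        np.add.at(wsum, flat, w[okm])

    covered = wsum > 1e-12
    outv = np.full(image.shape, float(background)).reshape(-1)
    outv[covered] = acc[covered] / wsum[covered]
    covered3 = covered.reshape(image.shape)
    if fill_holes_within is not None:
        holes = fill_holes_within & ~covered3
        n_holes = int(holes.sum())
        if n_holes:
            warnings.warn(f"filling {n_holes} uncovered voxels from nearest covered neighbor")
            _, nearest = ndimage.distance_transform_edt(
                ~covered3, sampling=image.spacing, return_indices=True
            )
            out3 = outv.reshape(image.shape)
            out3[holes] = out3[tuple(n[holes] for n in nearest)]
    return ScalarImage3D(outv.reshape(image.shape), image.spacing, image.origin)


def mask_with_region(
    image: ScalarImage3D, labels: LabelImage3D, region: str, background: float = BACKGROUND_VALUE
) -> ScalarImage3D:
    """Zero (background) everything outside a named region."""
    if not image.grid_matches(labels):
        raise ValueError("image and label grids differ")
    mask = labels.region_mask(region)
    out = np.full(image.shape, float(background))
    out[mask] = image.voxels[mask]
    return ScalarImage3D(out, image.spacing, image.origin)


def assign_resection_background(
    image: ScalarImage3D, labels: LabelImage3D, background: float = BACKGROUND_VALUE
) -> ScalarImage3D:
    """Set exactly the resected voxels to the background value (idempotent)."""
    if not image.grid_matches(labels):
        raise ValueError("image and label grids differ")
    resected = labels.region_mask("resected")
    out = image.voxels.copy()
    out[resected] = background
    return ScalarImage3D(out, image.spacing, image.origin)
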