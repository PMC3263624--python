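"""Edge-based validation: Canny edge maps and the modified Hausdorff distance.

Registration quality between two images is measured on the point sets of
their Canny edges (extracted inside a region mask, e.g. the whole-brain
region with skull and external CSF masked out) with the modified Hausdorff
distance

    H(A, B) = max(h(A, B), h(B, A)),   h(A, B) = (1/N_a) sum_a d(a, B),

the maximum of the two directed *mean* closest-point distances; averaging
makes the measure robust to outlier edge voxels from image noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import feature

from .core_mesh import LabelImage3D, ScalarImage3D


@dataclass
class EdgeMap:
    """Edge-voxel world coordinates (mm) extracted within a region mask."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)

    def translated(self, t) -> "EdgeMap":
        return EdgeMap(self.points + np.asarray(t, dtype=float))


def canny_edge_map(
    image: ScalarImage3D,
    labels: LabelImage3D | None = None,
    region: str = "whole_brain",
    mask: np.ndarray | None = None,
    sigma: float = 1.0,
    low_quantile: float = 0.70,
    high_quantile: float = 0.90,
) -> EdgeMap:
    """Slice-wise 2-D Canny edges of a masked image, as world points.

    Hysteresis thresholds sit at the given quantiles of the slice gradient
    magnitude.  An empty result is allowed (constant image) but makes the
    Hausdorff distance downstream undefined.
    """
    if mask is None:
        if labels is None:
            mask = np.ones(image.shape, dtype=bool)
        else:
            if not image.grid_matches(labels):
                raise ValueError("image and label grids differ")
            mask = labels.region_mask(region)
    if not mask.any():
        raise ValueError("empty region mask")
    pts = []
    for k in range(image.shape[2]):
        m = mask[:, :, k]
        if not m.any():
            continue
        # Mask the intensities (skull/background removed), then detect on the
        # masked slice so the region boundary itself is an edge; thresholds
        # come from the gradient-magnitude quantiles of the active pixels.
        sl = np.where(m, image.voxels[:, :, k], 0.0)
        if np.ptp(sl) == 0:
            continue
        gx = ndimage.gaussian_filter(sl, sigma, order=[1, 0])
        gy = ndimage.gaussian_filter(sl, sigma, order=[0, 1])
        gmag = np.hypot(gx, gy)
        region = ndimage.binary_dilation(m, iterations=2)
        active = gmag[region & (gmag > 1e-12)]
        if active.size == 0:
            continue
        lo, hi = np.quantile(active, [low_quantile, high_quantile])
        edges = feature.canny(sl, sigma=sigma, low_threshold=lo, high_threshold=hi)
        edges &= region
        ii, jj = np.nonzero(edges)
        if len(ii):
            pts.append(np.column_stack([ii, jj, np.full(len(ii), k)]))
    if not pts:
        return EdgeMap(np.zeros((0, 3)))
    idx = np.vstack(pts)
    return EdgeMap(image.voxel_to_world(idx))


def directed_hausdorff_mean(A: EdgeMap, B: EdgeMap) -> float:
    """h(A, B): mean over A of the distance to the closest point of B (mm)."""
    if len(A) == 0 or len(B) == 0:
        raise ValueError("empty edge set")
    tree = cKDTree(B.points)
    d, _ = tree.query(A.points)
    return float(d.mean())


def modified_hausdorff(A: EdgeMap, B: EdgeMap) -> float:
    """H(A, B) = max(h(A, B), h(B, A)), symmetric by construction (mm)."""
    return max(directed_hausdorff_mean(A, B), directed_hausdorff_mean(B, A))


def tumor_neighborhood_mask(labels_at_time1: LabelImage3D, margin: float = 25.0) -> np.ndarray:
    """Tumor region of the first image dilated by ``margin`` mm.

    Euclidean, anisotropy-aware dilation, intersected with the whole-brain
    region (plus the resected cavity, which replaces tumor tissue in later
    images but remains part of the neighborhood of interest).
    """
    tumor = labels_at_time1.region_mask("tumor")
    if not tumor.any():
        raise ValueError("tumor region is empty")
    if margin > 0:
        dist = ndimage.distance_transform_edt(~tumor, sampling=labels_at_time1.spacing)
        grown = dist <= margin
    else:
        grown = tumor
    brainish = labels_at_time1.region_mask("whole_brain") | labels_at_time1.region_mask("resected")
    return grown & brainish
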