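"""End-to-end serial update of intraoperative images.

The pipeline builds the biomechanical model once from the first image's
labels and then, for each consecutive image pair, estimates surface
landmark displacements and deforms the model:

* ``shift`` interval — FEM, driven by the whole-brain boundary and the
  internal tumor boundary (no tissue discontinuity yet);
* first ``resection`` interval — FEM, driven by the healthy-brain boundary
  only; the removed volume is reflected by background assignment in the
  warped image, not by a discontinuity;
* later ``resection`` intervals — XFEM, with the discontinuity taken from
  the previous image's cavity boundary, mapped back to the initial
  configuration through the accumulated displacement.

Landmarks are always tracked between the next-to-last and last acquired
images of the pair under consideration, every solve runs on the initial
mesh (no remeshing), and increments accumulate by superposition.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

import yaml

from .core_mesh import (
    LabelImage3D,
    MaterialLaw,
    ScalarImage3D,
    TetMesh,
    TriSurface,
    extract_boundary_surface,
    laplacian_smooth_surface,
    tetrahedralize_labeled_grid,
)
from .fem_core import BoundaryConditionSet, accumulate_increments, solve_fem
from .image_warping import (
    assign_resection_background,
    forward_warp_overlap_weighted,
    mask_with_region,
    mesh_displacement_to_voxel_field,
)
from .surface_tracking import (
    active_surface_evolve,
    compute_distance_map,
    local_rigid_icp_prealign,
    smooth_displacement_knn,
    transfer_to_mesh_boundary,
)
from .validation_metrics import canny_edge_map, modified_hausdorff, tumor_neighborhood_mask
from .xfem_core import CrackSurface, build_enrichment, xfem_assemble_solve


@dataclass
class PipelineConfig:
    """All tunable defaults of the serial pipeline (units: mm unless noted)."""

    young_modulus: float = 3000.0      # Pa; solution is independent of it
    poisson_ratio: float = 0.45
    target_edge: float = 5.0           # lattice cell size of the tet mesh
    knn_neighbors: int = 8             # displacement smoothing (five to ten)
    as_step: float = 0.3               # active-surface step (dimensionless)
    as_alpha: float = 0.2              # internal Laplacian weight
    as_max_iters: int = 200
    as_tol: float = 1e-3               # mm mean motion
    enrichment_kind: str = "hole"      # 'hole' or 'heaviside'
    canny_sigma: float = 1.0           # voxels
    canny_low_q: float = 0.70
    canny_high_q: float = 0.90
    tumor_margin: float = 25.0         # neighborhood mask dilation
    crack_smooth_iters: int = 5
    background: float = 0.0
    max_bc_gap: float | None = None    # default 1.5 * target_edge

    @property
    def material(self) -> MaterialLaw:
        return MaterialLaw(self.young_modulus, self.poisson_ratio)

    @property
    def bc_gap(self) -> float:
        return self.max_bc_gap if self.max_bc_gap is not None else 1.5 * self.target_edge

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class CaseTimeline:
    """Ordered image series with segmentations and interval deformation types.

    ``landmarks`` (optional) holds one corresponding landmark point list per
    image (world mm); when present, ``run_case`` rigidly co-registers every
    image onto the first one before nonrigid modeling.
    """

    images: list[ScalarImage3D]
    labels: list[LabelImage3D]
    interval_types: list[str]
    config: PipelineConfig = field(default_factory=PipelineConfig)
    landmarks: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if len(self.images) < 2:
            raise ValueError("a timeline needs at least two images")
        if len(self.labels) != len(self.images):
            raise ValueError("one label volume per image required")
        if len(self.interval_types) != len(self.images) - 1:
            raise ValueError("one interval type per consecutive image pair required")
        for t in self.interval_types:
            if t not in {"shift", "resection"}:
                raise ValueError(f"unknown interval type {t!r}")
        for img, lab in zip(self.images, self.labels):
            if not img.grid_matches(lab):
                raise ValueError("image and label grids differ within the timeline")
        if self.landmarks is not None and len(self.landmarks) != len(self.images):
            raise ValueError("one landmark list per image required")


def rigidly_coregister(timeline: CaseTimeline) -> CaseTimeline:
    """Resample every image/label pair onto the first image's frame.

    Uses the closed-form rigid landmark fit between each image's landmark
    list and the first image's; without landmarks the timeline is returned
    unchanged (images assumed pre-registered, e.g. the phantom).
    """
    if timeline.landmarks is None:
        return timeline
    from .rigid_registration import fit_landmark_transform

    ref_img = timeline.images[0]
    sp1 = np.asarray(ref_img.spacing)
    o1 = np.asarray(ref_img.origin)
    images = [timeline.images[0]]
    labels = [timeline.labels[0]]
    for k in range(1, len(timeline.images)):
        t = fit_landmark_transform(timeline.landmarks[k], timeline.landmarks[0],
                                   allow_scale=False)
        inv = t.inverse()
        img_k = timeline.images[k]
        lab_k = timeline.labels[k]
        sp_k = np.asarray(img_k.spacing)
        o_k = np.asarray(img_k.origin)
        # input voxel index = A @ output voxel index + b
        A = (inv.scale * inv.rotation * sp1[None, :]) / sp_k[:, None]
        b = (inv.apply(o1) - o_k) / sp_k
        vox = ndimage.affine_transform(img_k.voxels, A, offset=b, order=1, cval=0.0)
        lab = ndimage.affine_transform(lab_k.labels, A, offset=b, order=0, cval=0)
        images.append(ScalarImage3D(vox, ref_img.spacing, ref_img.origin))
        labels.append(LabelImage3D(lab, lab_k.legend, ref_img.spacing, ref_img.origin))
    return CaseTimeline(images, labels, list(timeline.interval_types), timeline.config)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def boundary_surface_from_mask(
    mask: np.ndarray,
    spacing,
    origin=(0.0, 0.0, 0.0),
    smooth_iters: int = 0,
) -> TriSurface:
    """Triangulated boundary of a voxel mask, normals pointing out of the mask.

    Faces between inside and outside voxels are emitted on the voxel-corner
    lattice and optionally Laplacian-smoothed (connectivity and orientation
    preserved).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    shape = np.asarray(mask.shape)
    corner_strides = np.array(
        [(shape[1] + 1) * (shape[2] + 1), shape[2] + 1, 1], dtype=np.int64
    )

    tri_keys = []
    for axis in range(3):
        b = (axis + 1) % 3
        c = (axis + 2) % 3
        for sign in (1, -1):
            shifted = np.roll(mask, -sign, axis=axis)
            # voxels at the array edge face outside
            edge = [slice(None)] * 3
            edge[axis] = -1 if sign > 0 else 0
            shifted[tuple(edge)] = False
            faces = mask & ~shifted
            vi = np.argwhere(faces)
            if len(vi) == 0:
                continue
            base = vi.copy()
            base[:, axis] += (sign + 1) // 2  # corner layer on the face side
            def corner(ob, oc):
                cidx = base.copy()
                cidx[:, b] += ob
                cidx[:, c] += oc
                return cidx @ corner_strides
            p00, p10, p01, p11 = corner(0, 0), corner(1, 0), corner(0, 1), corner(1, 1)
            if sign > 0:
                tri_keys.append(np.stack([p00, p10, p11], axis=1))
                tri_keys.append(np.stack([p00, p11, p01], axis=1))
            else:
                tri_keys.append(np.stack([p00, p11, p10], axis=1))
                tri_keys.append(np.stack([p00, p01, p11], axis=1))
    tris = np.vstack(tri_keys)
    used, inv = np.unique(tris, return_inverse=True)
    ci = np.stack(np.unravel_index(used, tuple(shape + 1)), axis=1)
    verts = origin + (ci - 0.5) * spacing
    surf = TriSurface(verts, inv.reshape(-1, 3))
    if smooth_iters:
        surf = laplacian_smooth_surface(surf, smooth_iters, 0.5)
    surf.compute_vertex_normals()
    return surf


def interpolate_in_mesh(
    points: np.ndarray,
    node_coords: np.ndarray,
    tets: np.ndarray,
    nodal_values: np.ndarray,
    k: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric interpolation of a nodal field at arbitrary points.

    Points outside every candidate tet take the least-bad candidate
    (nearest-tet extrapolation) and are flagged False in the second return.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    cent = node_coords[tets].mean(axis=1)
    tree = cKDTree(cent)
    k = min(k, len(tets))
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    x0 = node_coords[tets[cand, 0]]                      # (P, k, 3)
    T = np.transpose(
        node_coords[tets[cand, 1:]] - x0[:, :, None, :], (0, 1, 3, 2)
    )                                                    # (P, k, 3, 3) columns = edges
    Tinv = np.linalg.inv(T)
    lam123 = np.einsum("pkij,pkj->pki", Tinv, points[:, None, :] - x0)
    lam = np.concatenate([1 - lam123.sum(axis=-1, keepdims=True), lam123], axis=-1)
    worst = lam.min(axis=-1)                             # (P, k)
    best = np.argmax(worst, axis=1)
    sel = np.arange(len(points))
    lam_b = lam[sel, best]                               # (P, 4)
    tet_b = cand[sel, best]
    inside = worst[sel, best] >= -1e-9
    vals = np.einsum("pa,paj->pj", lam_b, nodal_values[tets[tet_b]])
    return vals, inside


# ---------------------------------------------------------------------------
# Model construction and per-interval tracking
# ---------------------------------------------------------------------------

@dataclass
class BiomechanicalModel:
    """The mesh built from the first image plus its tracked boundary surfaces."""

    mesh: TetMesh
    law: MaterialLaw
    whole_surface: TriSurface
    whole_node_ids: np.ndarray
    healthy_surface: TriSurface
    healthy_node_ids: np.ndarray
    tumor_patch_tris: np.ndarray      # triangle indices of healthy_surface
    tumor_patch_node_ids: np.ndarray  # mesh node ids of the tumor-facing portion


def build_model(labels1: LabelImage3D, config: PipelineConfig) -> BiomechanicalModel:
    mesh = tetrahedralize_labeled_grid(labels1, config.target_edge)
    whole = extract_boundary_surface(mesh, "all")
    healthy = extract_boundary_surface(mesh, "healthy_brain")
    whole_ids = whole.boundary_node_ids
    healthy_ids = healthy.boundary_node_ids

    # Tumor-facing portion of the healthy surface: its triangles that are
    # not part of the whole-brain (outer) boundary.
    outer_keys = {tuple(sorted(whole_ids[t])) for t in whole.triangles}
    patch = np.array(
        [i for i, t in enumerate(healthy.triangles)
         if tuple(sorted(healthy_ids[t])) not in outer_keys],
        dtype=np.int64,
    )
    patch_nodes = (
        np.unique(healthy_ids[np.unique(healthy.triangles[patch])])
        if len(patch) else np.zeros(0, dtype=np.int64)
    )
    return BiomechanicalModel(
        mesh=mesh,
        law=config.material,
        whole_surface=whole,
        whole_node_ids=whole_ids,
        healthy_surface=healthy,
        healthy_node_ids=healthy_ids,
        tumor_patch_tris=patch,
        tumor_patch_node_ids=patch_nodes,
    )


def _evolve(surface: TriSurface, dist_map, cfg: PipelineConfig) -> TriSurface:
    return active_surface_evolve(
        surface, dist_map,
        step=cfg.as_step, alpha_internal=cfg.as_alpha,
        max_iters=cfg.as_max_iters, tol=cfg.as_tol,
    )


def _track_region_surface(
    base_surface: TriSurface,
    deformed_vertices: np.ndarray,
    lab_cur: LabelImage3D,
    lab_next: LabelImage3D,
    region: str,
    cfg: PipelineConfig,
    icp_patch_tris: np.ndarray | None = None,
) -> tuple[TriSurface, np.ndarray]:
    """Track one region boundary between two images.

    The model boundary (posed at ``deformed_vertices``) is first relaxed
    onto the current image's boundary, optionally pre-aligned rigidly along
    the internal tumor boundary with ICP, then evolved onto the next
    image's boundary.  Returns the relaxed current surface and the smoothed
    per-vertex displacement to the next surface.
    """
    init = TriSurface(deformed_vertices.copy(), base_surface.triangles.copy())
    d_cur = compute_distance_map(lab_cur, region)
    surf_cur = _evolve(init, d_cur, cfg)

    start = surf_cur.copy()
    if icp_patch_tris is not None and len(icp_patch_tris):
        tumor_mask = lab_next.region_mask("tumor") | lab_next.region_mask("resected")
        if tumor_mask.any():
            target = boundary_surface_from_mask(
                tumor_mask, lab_next.spacing, lab_next.origin, smooth_iters=2
            )
            pverts = np.unique(start.triangles[icp_patch_tris])
            patch = TriSurface(start.vertices[pverts], np.zeros((0, 3), dtype=np.int64))
            transform = local_rigid_icp_prealign(patch, target)
            start.vertices[pverts] = transform.apply(start.vertices[pverts])

    d_next = compute_distance_map(lab_next, region)
    surf_next = _evolve(start, d_next, cfg)
    disp = smooth_displacement_knn(
        surf_next.vertices - surf_cur.vertices, surf_cur, cfg.knn_neighbors
    )
    return surf_cur, disp


def _boundary_bcs(
    model: BiomechanicalModel,
    node_ids: np.ndarray,
    accumulated: np.ndarray,
    surf_cur: TriSurface,
    disp: np.ndarray,
    cfg: PipelineConfig,
) -> BoundaryConditionSet:
    pos = model.mesh.node_coords[node_ids] + accumulated[node_ids]
    return transfer_to_mesh_boundary(
        disp, surf_cur, model.mesh, node_ids, node_positions=pos, max_gap=cfg.bc_gap
    )


def model_brain_shift(
    lab_cur: LabelImage3D,
    lab_next: LabelImage3D,
    model: BiomechanicalModel,
    accumulated: np.ndarray,
    cfg: PipelineConfig,
) -> tuple[np.ndarray, dict]:
    """FEM increment for a shift interval (whole-brain + tumor boundaries)."""
    wsurf, wdisp = _track_region_surface(
        model.whole_surface,
        model.mesh.node_coords[model.whole_node_ids] + accumulated[model.whole_node_ids],
        lab_cur, lab_next, "whole_brain", cfg,
    )
    bcs = _boundary_bcs(model, model.whole_node_ids, accumulated, wsurf, wdisp, cfg)

    if len(model.tumor_patch_node_ids):
        hsurf, hdisp = _track_region_surface(
            model.healthy_surface,
            model.mesh.node_coords[model.healthy_node_ids]
            + accumulated[model.healthy_node_ids],
            lab_cur, lab_next, "healthy_brain", cfg,
            icp_patch_tris=model.tumor_patch_tris,
        )
        tumor_bcs = _boundary_bcs(
            model, model.tumor_patch_node_ids, accumulated, hsurf, hdisp, cfg
        )
        bcs.entries.update(tumor_bcs.entries)

    inc = solve_fem(model.mesh, model.law, bcs)
    return inc, {"n_bcs": len(bcs), "method": "FEM"}


def _healthy_boundary_bcs(
    lab_cur: LabelImage3D,
    lab_next: LabelImage3D,
    model: BiomechanicalModel,
    accumulated: np.ndarray,
    cfg: PipelineConfig,
) -> BoundaryConditionSet:
    hsurf, hdisp = _track_region_surface(
        model.healthy_surface,
        model.mesh.node_coords[model.healthy_node_ids] + accumulated[model.healthy_node_ids],
        lab_cur, lab_next, "healthy_brain", cfg,
        icp_patch_tris=model.tumor_patch_tris,
    )
    return _boundary_bcs(model, model.healthy_node_ids, accumulated, hsurf, hdisp, cfg)


def model_first_resection(
    lab_cur: LabelImage3D,
    lab_next: LabelImage3D,
    model: BiomechanicalModel,
    accumulated: np.ndarray,
    cfg: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """FEM increment for the first resection (healthy-brain boundary only).

    No discontinuity is introduced; the removal is modeled by the resulting
    deformation plus background assignment in the warped image.  Returns
    the increment, the resected voxel mask of the next image (source of the
    next interval's discontinuity), and an info dict.
    """
    bcs = _healthy_boundary_bcs(lab_cur, lab_next, model, accumulated, cfg)
    inc = solve_fem(model.mesh, model.law, bcs)
    resected = lab_next.region_mask("resected")
    return inc, resected, {"n_bcs": len(bcs), "method": "FEM"}


def crack_from_cavity(
    lab_cur: LabelImage3D,
    model: BiomechanicalModel,
    accumulated: np.ndarray,
    cfg: PipelineConfig,
) -> CrackSurface | None:
    """Discontinuity surface of the current image's cavity, in the initial frame.

    The cavity boundary is extracted from the resected voxel mask, smoothed,
    and mapped back to the initial configuration by inverting the
    accumulated displacement (fixed-point iteration on the initial mesh).
    Normals point out of the cavity, i.e. away from the removed side.
    """
    mask = lab_cur.region_mask("resected")
    if not mask.any():
        return None
    surf = boundary_surface_from_mask(
        mask, lab_cur.spacing, lab_cur.origin, smooth_iters=cfg.crack_smooth_iters
    )
    Y = surf.vertices
    X = Y.copy()
    for _ in range(4):
        u, _inside = interpolate_in_mesh(
            X, model.mesh.node_coords, model.mesh.tets, accumulated
        )
        X = Y - u
    return CrackSurface(TriSurface(X, surf.triangles.copy()), closed=True)


def model_later_resection(
    lab_cur: LabelImage3D,
    lab_next: LabelImage3D,
    model: BiomechanicalModel,
    accumulated: np.ndarray,
    cfg: PipelineConfig,
) -> tuple[np.ndarray, dict]:
    """XFEM increment for a later resection (discontinuity from the prior cavity)."""
    bcs = _healthy_boundary_bcs(lab_cur, lab_next, model, accumulated, cfg)
    crack = crack_from_cavity(lab_cur, model, accumulated, cfg)
    if crack is None:
        warnings.warn("no prior cavity found; falling back to FEM (results identical)")
        inc = solve_fem(model.mesh, model.law, bcs)
        return inc, {"n_bcs": len(bcs), "method": "FEM(fallback)"}
    enrichment = build_enrichment(model.mesh, crack, cfg.enrichment_kind)
    if enrichment.n_enriched == 0 and not enrichment.cut_tets:
        warnings.warn("cavity intersects no element support; XFEM reduces to FEM")
    sol = xfem_assemble_solve(
        model.mesh, model.law, crack, cfg.enrichment_kind, bcs, enrichment=enrichment
    )
    info = {"n_bcs": len(bcs), "method": "XFEM", "enrichment": enrichment.report()}
    return sol.u, info


# ---------------------------------------------------------------------------
# Full case run
# ---------------------------------------------------------------------------

INTERVAL_NAMES = ["brain_shift", "1st_resection", "2nd_resection", "3rd_resection",
                  "4th_resection", "5th_resection"]


@dataclass
class CaseResult:
    model: BiomechanicalModel
    increments: list[np.ndarray]
    accumulated: list[np.ndarray]          # accumulated[k] = sum of increments 0..k
    pairwise_warped: list[ScalarImage3D]   # I_k^w, registered toward I_{k+1}
    cumulative_warped: list[ScalarImage3D] # I_{1,k}^w
    tables: dict
    infos: list[dict]
    config: PipelineConfig
    log: list[str]


def _interval_name(k: int, interval_types: list[str]) -> str:
    if interval_types[k] == "shift":
        return "brain_shift"
    n_res = sum(1 for t in interval_types[: k + 1] if t == "resection")
    return INTERVAL_NAMES[min(n_res, len(INTERVAL_NAMES) - 1)]


def run_case(timeline: CaseTimeline) -> CaseResult:
    """Run the full serial pipeline on a timeline; deterministic given inputs."""
    cfg = timeline.config
    had_landmarks = timeline.landmarks is not None
    timeline = rigidly_coregister(timeline)
    imgs, labs = timeline.images, timeline.labels
    log: list[str] = []
    if had_landmarks:
        log.append("rigidly co-registered all images to I_1 from landmarks")
    model = build_model(labs[0], cfg)
    log.append(
        f"model: {model.mesh.n_nodes} nodes, {model.mesh.n_tets} tets, "
        f"{3 * model.mesh.n_nodes} FEM DOFs"
    )

    increments: list[np.ndarray] = []
    accumulated: list[np.ndarray] = []
    infos: list[dict] = []
    acc = np.zeros((model.mesh.n_nodes, 3))
    prior_resection = False
    for k, itype in enumerate(timeline.interval_types):
        lab_cur, lab_next = labs[k], labs[k + 1]
        name = _interval_name(k, timeline.interval_types)
        if itype == "shift":
            inc, info = model_brain_shift(lab_cur, lab_next, model, acc, cfg)
        elif not prior_resection:
            inc, _resected, info = model_first_resection(lab_cur, lab_next, model, acc, cfg)
            prior_resection = True
        else:
            inc, info = model_later_resection(lab_cur, lab_next, model, acc, cfg)
        increments.append(inc)
        acc = acc + inc
        accumulated.append(acc.copy())
        info["interval"] = name
        infos.append(info)
        log.append(
            f"{name}: {info['method']}, {info['n_bcs']} BC nodes, "
            f"max increment {np.linalg.norm(inc, axis=1).max():.2f} mm"
        )

    pairwise: list[ScalarImage3D] = []
    cumulative: list[ScalarImage3D] = []
    for k in range(len(increments)):
        lab_next = labs[k + 1]
        brain_next = lab_next.region_mask("whole_brain")

        pose = model.mesh.node_coords + (accumulated[k - 1] if k else 0.0)
        vf, _ = mesh_displacement_to_voxel_field(
            model.mesh, increments[k], imgs[k], node_positions=pose
        )
        src = mask_with_region(imgs[k], labs[k], "whole_brain", cfg.background)
        w = forward_warp_overlap_weighted(src, vf, cfg.background, fill_holes_within=brain_next)
        w = mask_with_region(w, lab_next, "whole_brain", cfg.background)
        w = assign_resection_background(w, lab_next, cfg.background)
        pairwise.append(w)

        vfc, _ = mesh_displacement_to_voxel_field(model.mesh, accumulated[k], imgs[0])
        src1 = mask_with_region(imgs[0], labs[0], "whole_brain", cfg.background)
        wc = forward_warp_overlap_weighted(src1, vfc, cfg.background, fill_holes_within=brain_next)
        wc = mask_with_region(wc, lab_next, "whole_brain", cfg.background)
        wc = assign_resection_background(wc, lab_next, cfg.background)
        cumulative.append(wc)

    tables = hausdorff_tables(timeline, pairwise, cumulative)
    return CaseResult(
        model=model,
        increments=increments,
        accumulated=accumulated,
        pairwise_warped=pairwise,
        cumulative_warped=cumulative,
        tables=tables,
        infos=infos,
        config=cfg,
        log=log,
    )


def hausdorff_tables(
    timeline: CaseTimeline,
    pairwise: list[ScalarImage3D],
    cumulative: list[ScalarImage3D],
) -> dict:
    """Both validation protocols, each on the whole-brain and tumor-neighborhood masks.

    Pairwise: H(I_k, I_{k+1}) vs H(I_k^w, I_{k+1}).  Cumulative:
    H(I_1, I_{k+1}) vs H(I_{1,k}^w, I_{k+1}) — the amplification protocol.
    """
    cfg = timeline.config
    imgs, labs = timeline.images, timeline.labels
    nb = tumor_neighborhood_mask(labs[0], cfg.tumor_margin)

    def edges(image, mask):
        return canny_edge_map(
            image, mask=mask, sigma=cfg.canny_sigma,
            low_quantile=cfg.canny_low_q, high_quantile=cfg.canny_high_q,
        )

    rows = {"pairwise": [], "cumulative": []}
    for k in range(len(pairwise)):
        name = _interval_name(k, timeline.interval_types)
        wb_cur = labs[k].region_mask("whole_brain")
        wb_next = labs[k + 1].region_mask("whole_brain")
        wb_first = labs[0].region_mask("whole_brain")
        for scope, m_cur, m_next, m_first in (
            ("whole_brain", wb_cur, wb_next, wb_first),
            ("tumor_neighborhood", wb_cur & nb, wb_next & nb, wb_first & nb),
        ):
            e_next = edges(imgs[k + 1], m_next)
            rows["pairwise"].append({
                "interval": name, "scope": scope,
                "H_rigid": modified_hausdorff(edges(imgs[k], m_cur), e_next),
                "H_nonrigid": modified_hausdorff(edges(pairwise[k], m_next), e_next),
            })
            rows["cumulative"].append({
                "interval": name, "scope": scope,
                "H_rigid": modified_hausdorff(edges(imgs[0], m_first), e_next),
                "H_nonrigid": modified_hausdorff(edges(cumulative[k], m_next), e_next),
            })
    return rows


def save_tables(tables: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "hausdorff.json", "w") as fh:
        json.dump(tables, fh, indent=2)
    for proto, rows in tables.items():
        if not rows:
            continue
        with open(outdir / f"hausdorff_{proto}.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
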