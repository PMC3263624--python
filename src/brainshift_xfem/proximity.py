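"""Closest-point queries on triangulated surfaces with signed sides.

Provides exact point-to-triangle projection over k-nearest candidate
triangles (k-d tree on triangle centroids) and the angle-weighted
pseudonormal of the closest feature, which yields a robust side sign
``(x - x*) . e_n`` for watertight surfaces and extends an open surface
past its front along the nearest feature.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core_mesh import TriSurface


def closest_point_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Vectorized closest point on triangles (a, b, c) for points p.

    All inputs (n, 3).  Returns ``(cp, bary)`` with barycentric coordinates
    ordered like the triangle vertices.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    n = len(p)
    bary = np.zeros((n, 3))
    done = np.zeros(n, dtype=bool)

    def assign(mask, ba, bb, bc):
        m = mask & ~done
        bary[m, 0] = np.broadcast_to(ba, mask.shape)[m] if np.ndim(ba) else ba
        bary[m, 1] = np.broadcast_to(bb, mask.shape)[m] if np.ndim(bb) else bb
        bary[m, 2] = np.broadcast_to(bc, mask.shape)[m] if np.ndim(bc) else bc
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), 1.0, 0.0, 0.0)                      # vertex a
    assign((d3 >= 0) & (d4 <= d3), 0.0, 1.0, 0.0)                     # vertex b
    assign((d6 >= 0) & (d5 <= d6), 0.0, 0.0, 1.0)                     # vertex c
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        denom_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), 1.0 - v_ab, v_ab, 0.0)  # edge ab
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), 1.0 - w_ac, 0.0, w_ac)  # edge ac
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), 0.0, 1.0 - w_bc, w_bc)  # edge bc
    # interior
    m = ~done
    if m.any():
        denom = va[m] + vb[m] + vc[m]
        denom = np.where(denom == 0, 1.0, denom)
        v = vb[m] / denom
        w = vc[m] / denom
        bary[m, 0] = 1.0 - v - w
        bary[m, 1] = v
        bary[m, 2] = w
    cp = bary[:, [0]] * a + bary[:, [1]] * b + bary[:, [2]] * c
    return cp, bary


class SurfaceProximity:
    """Closest point / signed side queries against one TriSurface."""

    def __init__(self, surface: TriSurface, k_candidates: int = 32):
        self.surface = surface
        v = surface.vertices
        t = surface.triangles
        self._tri = t
        self._v = v
        self._centroids = v[t].mean(axis=1)
        self._tree = cKDTree(self._centroids)
        self._k = min(k_candidates, len(t))
        fn = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        nrm = np.linalg.norm(fn, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        self._face_n = fn / nrm
        self._vertex_n = self._angle_weighted_vertex_normals()
        self._edge_n = self._edge_normals()
        # characteristic triangle size, used for on-surface tolerances
        self.char_edge = float(np.sqrt(surface.triangle_areas().mean()) * 2) if len(t) else 1.0

    def _angle_weighted_vertex_normals(self) -> np.ndarray:
        v, t = self._v, self._tri
        out = np.zeros_like(v)
        for k in range(3):
            p0 = v[t[:, k]]
            e1 = v[t[:, (k + 1) % 3]] - p0
            e2 = v[t[:, (k + 2) % 3]] - p0
            n1 = np.linalg.norm(e1, axis=1)
            n2 = np.linalg.norm(e2, axis=1)
            cosang = np.clip(
                np.einsum("ij,ij->i", e1, e2) / np.where(n1 * n2 == 0, 1.0, n1 * n2), -1, 1
            )
            ang = np.arccos(cosang)
            np.add.at(out, t[:, k], ang[:, None] * self._face_n)
        nrm = np.linalg.norm(out, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        return out / nrm

    def _edge_normals(self) -> dict[tuple[int, int], np.ndarray]:
        t = self._tri
        acc: dict[tuple[int, int], np.ndarray] = {}
        for f in range(len(t)):
            for k in range(3):
                key = tuple(sorted((int(t[f, k]), int(t[f, (k + 1) % 3]))))
                acc[key] = acc.get(key, 0.0) + self._face_n[f]
        for key, n in acc.items():
            nn = np.linalg.norm(n)
            acc[key] = n / nn if nn > 0 else n
        return acc

    def closest(self, points: np.ndarray):
        """Closest surface points for query points.

        Returns ``(cp, dist, tri_idx, bary)``; ``dist`` is unsigned.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, cand = self._tree.query(points, k=self._k)
        cand = np.atleast_2d(cand)
        npts, k = cand.shape
        flat_p = np.repeat(points, k, axis=0)
        flat_t = cand.ravel()
        tri = self._tri[flat_t]
        cp, bary = closest_point_on_triangles(
            flat_p, self._v[tri[:, 0]], self._v[tri[:, 1]], self._v[tri[:, 2]]
        )
        d2 = np.einsum("ij,ij->i", flat_p - cp, flat_p - cp).reshape(npts, k)
        best = np.argmin(d2, axis=1)
        sel = np.arange(npts) * k + best
        return (
            cp[sel],
            np.sqrt(d2[np.arange(npts), best]),
            flat_t[sel],
            bary[sel],
        )

    def feature_normal(self, tri_idx: np.ndarray, bary: np.ndarray) -> np.ndarray:
        """Pseudonormal of the closest feature (face / edge / vertex)."""
        tol = 1e-9
        out = self._face_n[tri_idx].copy()
        zero = bary < tol
        nz = zero.sum(axis=1)
        for i in np.nonzero(nz == 2)[0]:  # vertex
            vtx = self._tri[tri_idx[i]][~zero[i]][0]
            out[i] = self._vertex_n[vtx]
        for i in np.nonzero(nz == 1)[0]:  # edge (opposite the zero coordinate)
            verts = self._tri[tri_idx[i]][~zero[i]]
            key = tuple(sorted((int(verts[0]), int(verts[1]))))
            out[i] = self._edge_n.get(key, out[i])
        return out

    def signed_values(self, points: np.ndarray) -> np.ndarray:
        """Signed side value (x - x*) . e_n with the feature pseudonormal."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        cp, _, tri_idx, bary = self.closest(points)
        en = self.feature_normal(tri_idx, bary)
        return np.einsum("ij,ij->i", points - cp, en)
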