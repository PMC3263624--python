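"""Point-based rigid/similarity landmark registration between images.

Successive intraoperative volumes are co-registered from corresponding
landmark point lists with the closed-form least-squares (SVD/Procrustes)
solution; reflections are excluded by sign correction.  Same-scanner
image-to-image registration uses a pure rigid fit (scale fixed to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RigidTransform:
    """x -> scale * R x + t, with R a proper rotation."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return self.scale * p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
            self.scale * other.scale,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation / self.scale, 1.0 / self.scale)

    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.scale * self.rotation
        M[:3, 3] = self.translation
        return M

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


def fit_landmark_transform(
    src: np.ndarray, dst: np.ndarray, allow_scale: bool = False
) -> RigidTransform:
    """Least-squares similarity/rigid transform mapping src onto dst.

    Closed-form Umeyama solution; requires >= 3 non-collinear pairs.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst, dtype=float).reshape(-1, 3)
    if src.shape != dst.shape:
        raise ValueError("src and dst must have the same length")
    n = len(src)
    if n < 3:
        raise ValueError("at least 3 landmark pairs are required")

    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    if np.linalg.matrix_rank(xs, tol=1e-9 * max(1.0, np.abs(xs).max())) < 2:
        raise ValueError("landmark configuration is collinear")

    C = xd.T @ xs / n
    U, S, Vt = np.linalg.svd(C)
    sign = np.sign(np.linalg.det(U @ Vt))
    Dm = np.diag([1.0, 1.0, sign])
    R = U @ Dm @ Vt
    if allow_scale:
        var_s = (xs ** 2).sum() / n
        scale = float(np.trace(np.diag(S) @ Dm) / var_s)
    else:
        scale = 1.0
    t = mu_d - scale * R @ mu_s
    return RigidTransform(R, t, scale)


def registration_residual(transform: RigidTransform, src: np.ndarray, dst: np.ndarray) -> float:
    """Root-mean-square landmark residual after applying the transform (mm)."""
    r = transform.apply(src) - np.asarray(dst, dtype=float)
    return float(np.sqrt((r ** 2).sum(axis=1).mean()))


def load_landmarks(path) -> np.ndarray:
    """Whitespace-delimited ``x y z`` landmark file, world mm."""
    pts = np.loadtxt(path, dtype=float)
    return pts.reshape(-1, 3)


def save_landmarks(path, points: np.ndarray) -> None:
    np.savetxt(path, np.asarray(points, dtype=float).reshape(-1, 3), fmt="%.9g")


def save_transform(path, transform: RigidTransform) -> None:
    np.savetxt(path, transform.matrix(), fmt="%.12g")


def load_transform(path) -> RigidTransform:
    M = np.loadtxt(path).reshape(4, 4)
    A = M[:3, :3]
    scale = float(np.cbrt(np.linalg.det(A)))
    return RigidTransform(A / scale, M[:3, 3], scale)
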