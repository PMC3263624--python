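"""Five-time-point synthetic phantom with known ground-truth deformations.

The phantom emulates the intraoperative image series the pipeline is built
for: a smooth-boundary "brain" ball containing an off-center "tumor" ball,
imaged five times.  Between images 1 and 2 the brain sags under a
compactly supported shift bump at the apex; images 3-5 show a resection
cavity growing through fixed volume fractions of the tumor, each
accompanied by a compactly supported relaxation field that pulls tissue
toward the cavity.  All deformation increments are analytic functions of
the initial (material) coordinates, so in the linear regime they compose
by summation and every interval's ground-truth voxel displacement field is
known exactly.

Intensities encode boundaries with a ~1 mm smooth transition (sub-voxel
boundary localization, as partial-volume averaging would give), plus
additive Gaussian noise.  Labels are generated from the same analytic
geometry, so segmentations are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .core_mesh import (
    BACKGROUND,
    DEFAULT_LEGEND,
    HEALTHY,
    RESECTED,
    TUMOR,
    LabelImage3D,
    ScalarImage3D,
)
from .serial_pipeline import CaseTimeline, PipelineConfig


@dataclass
class PhantomSpec:
    """Geometry, deformation and noise parameters of one phantom case.

    Defaults are the package's reference study conditions: a 64^3 grid at
    2 mm isotropic spacing, a 52 mm brain, a 12 mm tumor 18 mm off-center,
    a 5 mm apex shift (within the 4-7 mm range of intraoperative brain
    shift and below 10% of the brain radius, keeping strains small) and
    three resections removing 40/70/100% of the tumor volume.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_radius: float = 52.0
    tumor_offset: tuple[float, float, float] = (0.0, 0.0, 18.0)
    tumor_radius: float = 12.0
    shift_amplitude: float = 5.0
    shift_support: float = 45.0
    resection_fractions: tuple[float, ...] = (0.4, 0.7, 1.0)
    relax_amplitudes: tuple[float, ...] = (1.5, 1.2, 1.0)
    relax_support: float = 30.0
    noise_sd_frac: float = 0.02
    intensity_healthy: float = 100.0
    intensity_tumor: float = 160.0
    edge_width: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        off = np.linalg.norm(self.tumor_offset)
        if off + self.tumor_radius >= self.brain_radius:
            raise ValueError("tumor must lie strictly inside the brain")
        f = np.asarray(self.resection_fractions, dtype=float)
        if np.any(f <= 0) or np.any(f > 1) or np.any(np.diff(f) < 0):
            raise ValueError("resection fractions must be nondecreasing in (0, 1]")
        if len(self.relax_amplitudes) != len(f):
            raise ValueError("one relaxation amplitude per resection stage required")
        if self.shift_amplitude >= 0.1 * self.brain_radius + 1e-12:
            raise ValueError("shift amplitude outside the small-strain regime (<10% of radius)")

    @property
    def n_images(self) -> int:
        return 2 + len(self.resection_fractions)

    @property
    def brain_center(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    @property
    def tumor_center(self) -> np.ndarray:
        return self.brain_center + np.asarray(self.tumor_offset, dtype=float)

    def cavity_radius(self, stage: int) -> float:
        """Cavity radius realizing the stage's tumor-volume fraction (stage >= 1)."""
        return self.tumor_radius * float(self.resection_fractions[stage - 1]) ** (1.0 / 3.0)


def _wendland(q: np.ndarray) -> np.ndarray:
    """Wendland C2 bump: (1-q)^4 (4q+1) on [0, 1), 0 beyond."""
    q = np.clip(q, 0.0, 1.0)
    return (1.0 - q) ** 4 * (4.0 * q + 1.0)


def shift_field(spec: PhantomSpec, X: np.ndarray) -> np.ndarray:
    """Brain-shift increment: apex bump directed inward along -z (mm)."""
    apex = spec.brain_center + np.array([0.0, 0.0, spec.brain_radius])
    q = np.linalg.norm(X - apex, axis=-1) / spec.shift_support
    return -spec.shift_amplitude * _wendland(q)[..., None] * np.array([0.0, 0.0, 1.0])


def relaxation_field(spec: PhantomSpec, stage: int, X: np.ndarray) -> np.ndarray:
    """Post-resection relaxation: tissue collapses toward the cavity center.

    Radial profile 4q(1-q) vanishes at the center and at the support edge.
    """
    r = X - spec.tumor_center
    dist = np.linalg.norm(r, axis=-1)
    q = np.clip(dist / spec.relax_support, 0.0, 1.0)
    mag = 4.0 * q * (1.0 - q)
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.where(dist[..., None] > 1e-12, r / np.maximum(dist, 1e-12)[..., None], 0.0)
    return -float(spec.relax_amplitudes[stage - 1]) * mag[..., None] * rhat


def total_field(spec: PhantomSpec, upto_interval: int, X: np.ndarray) -> np.ndarray:
    """Sum of the first ``upto_interval`` increments at material points X."""
    u = np.zeros_like(X, dtype=float)
    if upto_interval >= 1:
        u += shift_field(spec, X)
    for s in range(1, upto_interval):
        u += relaxation_field(spec, s, X)
    return u


def _invert_map(spec: PhantomSpec, upto_interval: int, Y: np.ndarray, iters: int = 8) -> np.ndarray:
    """Material coordinates X with X + u(X) = Y, by fixed-point iteration."""
    X = Y.copy()
    for _ in range(iters):
        X = Y - total_field(spec, upto_interval, X)
    return X


def _smoothstep(d: np.ndarray, w: float) -> np.ndarray:
    """0 -> 1 transition of width ~2w around d = 0 (d positive inside)."""
    t = np.clip(d / (2.0 * w) + 0.5, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _anatomy_intensity(spec: PhantomSpec, X: np.ndarray, stage: int) -> np.ndarray:
    """Noise-free intensity at material points for a given resection stage (0 = none)."""
    db = spec.brain_radius - np.linalg.norm(X - spec.brain_center, axis=-1)
    dt = spec.tumor_radius - np.linalg.norm(X - spec.tumor_center, axis=-1)
    w = spec.edge_width
    inten = _smoothstep(db, w) * (
        spec.intensity_healthy
        + (spec.intensity_tumor - spec.intensity_healthy) * _smoothstep(dt, w)
    )
    if stage >= 1:
        dc = spec.cavity_radius(stage) - np.linalg.norm(X - spec.tumor_center, axis=-1)
        inten *= 1.0 - _smoothstep(dc, w)
    return inten


def _anatomy_labels(spec: PhantomSpec, X: np.ndarray, stage: int) -> np.ndarray:
    rb = np.linalg.norm(X - spec.brain_center, axis=-1)
    rt = np.linalg.norm(X - spec.tumor_center, axis=-1)
    lab = np.full(X.shape[:-1], BACKGROUND, dtype=np.int32)
    lab[rb < spec.brain_radius] = HEALTHY
    lab[(rb < spec.brain_radius) & (rt < spec.tumor_radius)] = TUMOR
    if stage >= 1:
        lab[(rb < spec.brain_radius) & (rt < spec.cavity_radius(stage))] = RESECTED
    return lab


def generate_case(
    spec: PhantomSpec, config: PipelineConfig | None = None
) -> tuple[CaseTimeline, list[np.ndarray]]:
    """Generate the five-image timeline and per-interval ground-truth fields.

    Returns ``(timeline, truth)`` where ``truth[k]`` is the k-th interval's
    displacement increment sampled at the voxel centers of the initial grid
    (shape ``(*shape, 3)``, mm, material coordinates).  All randomness
    derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    idx = np.indices(spec.shape).astype(float)
    Y = np.moveaxis(idx, 0, -1) * np.asarray(spec.spacing)  # voxel centers, origin 0

    images: list[ScalarImage3D] = []
    labels: list[LabelImage3D] = []
    noise_sd = spec.noise_sd_frac * spec.intensity_tumor
    for img_i in range(spec.n_images):
        stage = max(0, img_i - 1)  # image 3 (index 2) shows the 1st cavity
        X = _invert_map(spec, img_i, Y) if img_i else Y
        inten = _anatomy_intensity(spec, X, stage)
        inten = inten + rng.normal(0.0, noise_sd, size=inten.shape)
        images.append(ScalarImage3D(inten, spec.spacing))
        labels.append(
            LabelImage3D(_anatomy_labels(spec, X, stage), dict(DEFAULT_LEGEND), spec.spacing)
        )

    interval_types = ["shift"] + ["resection"] * len(spec.resection_fractions)
    truth = [shift_field(spec, Y)] + [
        relaxation_field(spec, s, Y) for s in range(1, len(spec.resection_fractions) + 1)
    ]
    timeline = CaseTimeline(
        images=images,
        labels=labels,
        interval_types=interval_types,
        config=config or PipelineConfig(),
    )
    return timeline, truth


def ground_truth_error(
    pred: np.ndarray, truth: np.ndarray, mask: np.ndarray
) -> dict[str, float]:
    """Per-voxel Euclidean error statistics of a predicted field over a mask (mm)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("field grids do not match")
    err = np.linalg.norm(pred - truth, axis=-1)[mask]
    if err.size == 0:
        raise ValueError("empty evaluation mask")
    return {
        "mean": float(err.mean()),
        "max": float(err.max()),
        "rms": float(np.sqrt((err ** 2).mean())),
        "n_voxels": int(err.size),
    }
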