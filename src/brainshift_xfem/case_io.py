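"""Case directories: a ``case.yaml`` manifest plus NIfTI volumes.

The manifest lists the image/label paths in acquisition order, the
interval deformation types, pipeline parameters, and (optionally)
ground-truth displacement fields when the case was generated by the
phantom module.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .mesh_io import (
    load_image_nifti,
    load_labels_nifti,
    load_voxel_field_nifti,
    save_image_nifti,
    save_labels_nifti,
    save_voxel_field_nifti,
)
from .serial_pipeline import CaseTimeline, PipelineConfig


def save_case_directory(
    timeline: CaseTimeline, outdir, truth_fields: list[np.ndarray] | None = None
) -> Path:
    """Write a self-contained case directory; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "images": [],
        "labels": [],
        "interval_types": list(timeline.interval_types),
        "config": timeline.config.to_dict(),
    }
    for i, (img, lab) in enumerate(zip(timeline.images, timeline.labels), start=1):
        ipath = f"image_{i}.nii.gz"
        lpath = f"labels_{i}.nii.gz"
        save_image_nifti(outdir / ipath, img)
        save_labels_nifti(outdir / lpath, lab)
        manifest["images"].append(ipath)
        manifest["labels"].append(lpath)
    if timeline.landmarks is not None:
        from .rigid_registration import save_landmarks

        manifest["landmarks"] = []
        for i, pts in enumerate(timeline.landmarks, start=1):
            lpath = f"landmarks_{i}.txt"
            save_landmarks(outdir / lpath, pts)
            manifest["landmarks"].append(lpath)
    if truth_fields is not None:
        manifest["truth_fields"] = []
        for k, f in enumerate(truth_fields, start=1):
            fpath = f"truth_increment_{k}.nii.gz"
            save_voxel_field_nifti(outdir / fpath, f, timeline.images[0].spacing,
                                   timeline.images[0].origin)
            manifest["truth_fields"].append(fpath)
    path = outdir / "case.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def load_case_directory(case_yaml) -> tuple[CaseTimeline, list[np.ndarray] | None]:
    """Load a case directory; returns (timeline, truth fields or None)."""
    case_yaml = Path(case_yaml)
    base = case_yaml.parent
    with open(case_yaml) as fh:
        manifest = yaml.safe_load(fh)
    images = [load_image_nifti(base / p) for p in manifest["images"]]
    labels = [load_labels_nifti(base / p) for p in manifest["labels"]]
    config = PipelineConfig.from_dict(manifest.get("config", {}))
    landmarks = None
    if manifest.get("landmarks"):
        from .rigid_registration import load_landmarks

        landmarks = [load_landmarks(base / p) for p in manifest["landmarks"]]
    timeline = CaseTimeline(images, labels, list(manifest["interval_types"]), config,
                            landmarks=landmarks)
    truth = None
    if manifest.get("truth_fields"):
        truth = [load_voxel_field_nifti(base / p) for p in manifest["truth_fields"]]
    return timeline, truth
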