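"""File formats: PointSet CSV, transform JSON, NIfTI volumes.

PointSets travel as CSV with header ``label,x_mm,y_mm,z_mm`` (UTF-8, decimal
point).  Transforms travel as JSON with a row-major rotation, translation,
scale, the residual statistics and a ``convention`` string naming the Euler
axis order.  Volumes are NIfTI-1; spacing comes from the header zooms and the
origin from the offset fields.  Machine outputs keep full double precision —
display rounding belongs to report rendering only.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .localization import VoxelGrid
from .registration import (
    PointSet,
    RegistrationResult,
    SimilarityTransform,
)

__all__ = [
    "EULER_CONVENTION",
    "read_pointset_csv",
    "write_pointset_csv",
    "read_transform_json",
    "write_transform_json",
    "read_nifti",
    "write_nifti",
]

EULER_CONVENTION = "intrinsic x-y-z: r = Rx(alpha) @ Ry(beta) @ Rz(gamma)"

POINTSET_COLUMNS = ["label", "x_mm", "y_mm", "z_mm"]


def read_pointset_csv(path: str | Path) -> PointSet:
    """Read a labelled point set from ``label,x_mm,y_mm,z_mm`` CSV."""
    df = pd.read_csv(path, dtype={"label": str})
    missing = [c for c in POINTSET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return PointSet(
        tuple(df["label"]), df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    )


def write_pointset_csv(points: PointSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "label": points.labels,
            "x_mm": points.coords[:, 0],
            "y_mm": points.coords[:, 1],
            "z_mm": points.coords[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_transform_json(
    result: RegistrationResult | SimilarityTransform, path: str | Path
) -> None:
    """Serialize a transform (optionally with residuals) to JSON."""
    if isinstance(result, RegistrationResult):
        transform = result.transform
        residual_e = result.residual_e
        per_point = list(map(float, result.per_point_residuals))
    else:
        transform = result
        residual_e = None
        per_point = None
    payload = {
        "rotation": transform.rotation.tolist(),
        "translation_mm": transform.translation.tolist(),
        "scale": transform.scale,
        "residual_e_mm": residual_e,
        "per_point_residuals_mm": per_point,
        "convention": EULER_CONVENTION,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_transform_json(path: str | Path) -> SimilarityTransform:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return SimilarityTransform(
        np.asarray(payload["rotation"], dtype=float),
        np.asarray(payload["translation_mm"], dtype=float),
        float(payload["scale"]),
    )


def write_nifti(volume: VoxelGrid, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a diagonal mm affine."""
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.intensities.astype(np.float32), affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> VoxelGrid:
    """Read a NIfTI-1 volume; spacing from the zooms, origin from the offsets.

    Only axis-aligned (diagonal-affine) volumes are supported — the rasterizer
    and scanners in this pipeline write them; anything else is refused rather
    than silently resampled.
    """
    img = nib.load(str(path))
    affine = img.affine
    if np.max(np.abs(affine[:3, :3] - np.diag(np.diag(affine[:3, :3])))) > 1e-6:
        raise ValueError(f"{path}: non-axis-aligned affine is not supported")
    spacing = np.diag(affine[:3, :3]).copy()
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: affine implies non-positive spacing")
    return VoxelGrid(
        np.asarray(img.dataobj, dtype=float), spacing, affine[:3, 3].copy()
    )
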