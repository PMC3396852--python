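"""Fiducial-sphere and cannula-tip localization in 3-D intensity volumes.

Bright spherical fiducials are found by thresholding, 26-connected component
labelling and background-subtracted intensity-weighted centroids; the weighted
centroid compensates the partial-volume "oval" appearance spheres acquire on
anisotropic voxel grids.  The cannula tip is the small hypointense volume left
by the infusion: within a user-supplied region of interest its darker Otsu
class is extracted and its unweighted geometric centroid reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu

from .registration import Point3, PointSet

__all__ = [
    "VoxelGrid",
    "FiducialDetection",
    "DetectionError",
    "TipNotFoundError",
    "AmbiguousMatchError",
    "detect_fiducials",
    "locate_tip",
    "match_fiducials",
]

#: Components smaller than this many voxels are treated as noise.
MIN_COMPONENT_VOXELS = 3

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


class DetectionError(RuntimeError):
    """Fewer candidate fiducial components found than expected."""


class TipNotFoundError(RuntimeError):
    """No hypointense component inside the region of interest."""


class AmbiguousMatchError(RuntimeError):
    """Optimal assignment left a detected/reference pair implausibly far apart."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D scalar intensity array with anisotropic spacing.

    Array axis 0, 1, 2 correspond to world x (sagittal), y (coronal),
    z (axial).  Voxel-centre convention with 0-based indices:
    ``world = origin + index * spacing``, everything in mm.
    """

    intensities: np.ndarray  # (nx, ny, nz)
    spacing: np.ndarray  # (3,) mm per axis
    origin: np.ndarray  # (3,) world mm of voxel (0, 0, 0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError("intensities must be a non-empty 3-D array")
        if not np.all(spacing > 0):
            raise ValueError("spacing components must be positive")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) (possibly fractional) voxel indices to world mm."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing


@dataclass(frozen=True)
class FiducialDetection:
    """One detected fiducial: weighted centroid, support size, integrated
    (background-subtracted) intensity."""

    centroid: Point3
    voxel_count: int
    total_intensity: float

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")
        if not self.total_intensity > 0:
            raise ValueError("total_intensity must be positive")


def detect_fiducials(
    volume: VoxelGrid,
    threshold: float,
    expected_count: int,
    min_voxels: int = MIN_COMPONENT_VOXELS,
) -> list[FiducialDetection]:
    """Detect bright spherical fiducials in a volume.

    Voxels strictly above ``threshold`` are grouped into 26-connected
    components; components with fewer than ``min_voxels`` voxels are rejected
    as noise.  Each surviving component contributes an intensity-weighted
    centroid in world mm, with weights taken relative to the volume's minimum
    intensity so a constant sub-threshold background does not bias the
    estimate.  The ``expected_count`` components of largest integrated
    intensity are returned, sorted brightest first.

    Raises
    ------
    DetectionError
        If fewer than ``expected_count`` components survive.
    """
    if expected_count < 1:
        raise ValueError("expected_count must be >= 1")
    arr = volume.intensities
    mask = arr > threshold
    labelled, n_comp = ndimage.label(mask, structure=_CONNECTIVITY_26)
    background = float(arr.min())

    detections: list[FiducialDetection] = []
    for comp in range(1, n_comp + 1):
        idx = np.argwhere(labelled == comp)
        if idx.shape[0] < min_voxels:
            continue
        weights = arr[tuple(idx.T)] - background
        total = float(weights.sum())
        if total <= 0:
            continue
        centroid_idx = (weights[:, None] * idx).sum(axis=0) / total
        centroid = Point3.from_array(volume.index_to_world(centroid_idx))
        detections.append(FiducialDetection(centroid, int(idx.shape[0]), total))

    if len(detections) < expected_count:
        raise DetectionError(
            f"expected {expected_count} fiducials but found {len(detections)} "
            f"components of >= {min_voxels} voxels above threshold {threshold}"
        )
    detections.sort(key=lambda d: d.total_intensity, reverse=True)
    return detections[:expected_count]


def locate_tip(
    volume: VoxelGrid, roi_centre: Point3, roi_radius: float
) -> Point3:
    """Locate the cannula tip as the centre of a hypointense volume.

    Within a spherical region of interest (world mm), intensities are split by
    Otsu's threshold; voxels of the darker class form candidate components
    (26-connected) and the largest component's unweighted geometric centroid is
    returned — the tip location is *defined* as the centre of that volume, so
    no intensity weighting is applied.

    Raises
    ------
    TipNotFoundError
        If the ROI misses the volume, has uniform intensity, or contains no
        hypointense component.
    """
    arr = volume.intensities
    idx = np.indices(arr.shape).reshape(3, -1).T
    world = volume.index_to_world(idx)
    centre = roi_centre.as_array()
    in_roi = np.linalg.norm(world - centre, axis=1) <= roi_radius
    if not in_roi.any():
        raise TipNotFoundError("region of interest does not intersect the volume")
    roi_mask = in_roi.reshape(arr.shape)
    vals = arr[roi_mask]
    if np.ptp(vals) == 0:
        raise TipNotFoundError("uniform-intensity region: no hypointensity to locate")
    thr = threshold_otsu(vals)
    dark = roi_mask & (arr < thr)
    if not dark.any():
        raise TipNotFoundError("no voxels below the hypointensity threshold in ROI")
    labelled, n_comp = ndimage.label(dark, structure=_CONNECTIVITY_26)
    sizes = ndimage.sum_labels(np.ones_like(arr), labelled, range(1, n_comp + 1))
    comp = int(np.argmax(sizes)) + 1
    comp_idx = np.argwhere(labelled == comp)
    centroid_idx = comp_idx.mean(axis=0)
    return Point3.from_array(volume.index_to_world(centroid_idx))


def match_fiducials(
    detected: list[Point3] | np.ndarray,
    reference: PointSet,
    gate_mm: float = 10.0,
) -> PointSet:
    """Order detected fiducials to correspond with a reference arc geometry.

    Both sets are centred on their centroids (removing any gross common
    offset) and matched one-to-one by minimum total squared distance
    (Hungarian assignment).  The returned PointSet carries the *original*
    detected coordinates, reordered and labelled to follow the reference.

    Raises
    ------
    AmbiguousMatchError
        If any matched pair is farther than ``gate_mm`` apart after centroid
        alignment — a sign of spurious or missing detections.
    """
    det = np.vstack(
        [p.as_array() if isinstance(p, Point3) else np.asarray(p, float) for p in detected]
    )
    if det.shape[0] != len(reference):
        raise ValueError(
            f"detected count {det.shape[0]} != reference count {len(reference)}"
        )
    det_c = det - det.mean(axis=0)
    ref_c = reference.coords - reference.coords.mean(axis=0)
    cost = ((ref_c[:, None, :] - det_c[None, :, :]) ** 2).sum(axis=2)
    ref_rows, det_cols = linear_sum_assignment(cost)
    order = np.empty(len(reference), dtype=int)
    order[ref_rows] = det_cols
    dists = np.sqrt(cost[ref_rows, det_cols])
    if np.any(dists > gate_mm):
        worst = reference.labels[int(np.argmax(dists))]
        raise AmbiguousMatchError(
            f"fiducial {worst!r} matched at {dists.max():.2f} mm "
            f"(> gate {gate_mm} mm) after centroid alignment"
        )
    return PointSet(reference.labels, det[order])
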