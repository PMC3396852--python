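"""Closed-form least-squares similarity registration of corresponding point sets.

Solves the absolute-orientation problem for two ordered sets of 3-D fiducial
coordinates: find the rotation ``r``, translation ``t`` and (optionally) scale
``s`` minimising ``sum_i || post_i - (s * r @ pre_i + t) ||^2``.  The solution
is Horn's closed-form unit-quaternion method — no iteration, no initial guess.

Coordinate convention throughout the package: ``x`` = sagittal, ``y`` =
coronal, ``z`` = axial, all in millimetres.  Euler angles compose intrinsically
in the order x, then y, then z: ``r = Rx(alpha) @ Ry(beta) @ Rz(gamma)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Point3",
    "PointSet",
    "EulerAngles",
    "SimilarityTransform",
    "RegistrationResult",
    "CorrespondenceError",
    "UnderdeterminedError",
    "DegenerateGeometryError",
    "horn_register",
    "apply_transform",
    "registration_residual",
    "compose_euler_rotation",
    "decompose_rotation",
]

#: Orthonormality / unit-determinant tolerance for rotation matrices.
ROTATION_TOL = 1e-9

#: Centered pre-set is degenerate (collinear) when its second-largest singular
#: value falls below this fraction of the largest.
COLLINEARITY_RTOL = 1e-6


class CorrespondenceError(ValueError):
    """Point sets of mismatched length cannot be registered point-to-point."""


class UnderdeterminedError(ValueError):
    """Fewer than three point pairs: nine constraints are required to pin
    down the seven (or six) degrees of freedom."""


class DegenerateGeometryError(ValueError):
    """Collinear fiducials leave a rotation about the line unconstrained."""


@dataclass(frozen=True)
class Point3:
    """A 3-D world coordinate in mm (x sagittal, y coronal, z axial)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValueError(f"non-finite coordinate in {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: Iterable[float]) -> "Point3":
        x, y, z = (float(v) for v in a)
        return cls(x, y, z)


@dataclass(frozen=True)
class PointSet:
    """Ordered, labelled fiducial/target coordinates in one scan space.

    Order defines correspondence: two point sets being registered must list
    matching fiducials at matching positions (use
    :func:`stereoreg.localization.match_fiducials` first if the order is
    unknown).
    """

    labels: tuple[str, ...]
    coords: np.ndarray  # (n, 3) float, mm

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {coords.shape}")
        if len(self.labels) != coords.shape[0]:
            raise ValueError("labels and coords length mismatch")
        if coords.shape[0] < 1:
            raise ValueError("a PointSet needs at least one point")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def points(self) -> list[Point3]:
        return [Point3.from_array(row) for row in self.coords]

    def point(self, label: str) -> Point3:
        return Point3.from_array(self.coords[self.labels.index(label)])

    @classmethod
    def from_points(
        cls, labels: Sequence[str], points: Sequence[Point3 | Sequence[float]]
    ) -> "PointSet":
        rows = [
            p.as_array() if isinstance(p, Point3) else np.asarray(p, float)
            for p in points
        ]
        return cls(tuple(labels), np.vstack(rows) if rows else np.empty((0, 3)))


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic x-y-z rotation angles in radians."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for v in (self.alpha, self.beta, self.gamma):
            if not math.isfinite(v):
                raise ValueError("Euler angles must be finite")


def _validate_rotation(r: np.ndarray, tol: float = ROTATION_TOL) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {r.shape}")
    if np.max(np.abs(r.T @ r - np.eye(3))) > tol:
        raise ValueError("rotation matrix is not orthonormal")
    if abs(np.linalg.det(r) - 1.0) > tol:
        raise ValueError("rotation matrix determinant is not +1")
    return r


@dataclass(frozen=True)
class SimilarityTransform:
    """Rotation + translation + isotropic scale mapping one scan space to
    another: ``p_post = s * r @ p_pre + t``."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,) mm
    scale: float = 1.0

    def __post_init__(self) -> None:
        r = _validate_rotation(self.rotation)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError("scale must be a positive finite number")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "scale", float(self.scale))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array (or a single 3-vector) of mm coordinates."""
        a = np.asarray(coords, dtype=float)
        return self.scale * a @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RegistrationResult:
    """A fitted transform with its fiducial registration error.

    ``residual_e`` is the root-mean-square per-fiducial residual distance
    (the "average re-positional error"); ``sum_squared_residuals`` is the raw
    summed squared misfit ``e^2 = sum_i dx_i^2 + dy_i^2 + dz_i^2`` for readers
    who want the un-averaged statistic.
    """

    transform: SimilarityTransform
    per_point_residuals: np.ndarray  # (n,) mm
    residual_e: float  # mm, RMS
    sum_squared_residuals: float  # mm^2

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "per_point_residuals", np.asarray(self.per_point_residuals, float)
        )


def compose_euler_rotation(angles: EulerAngles) -> np.ndarray:
    """Rotation matrix for intrinsic x-y-z angles: ``Rx(a) @ Ry(b) @ Rz(g)``."""
    ca, sa = math.cos(angles.alpha), math.sin(angles.alpha)
    cb, sb = math.cos(angles.beta), math.sin(angles.beta)
    cg, sg = math.cos(angles.gamma), math.sin(angles.gamma)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return rx @ ry @ rz


def decompose_rotation(r: np.ndarray, tol: float = 1e-8) -> EulerAngles:
    """Invert :func:`compose_euler_rotation`.

    Away from gimbal lock (|beta| = pi/2) the round trip reproduces ``r`` to
    ~1e-9.  At gimbal lock gamma is conventionally set to 0 and the remaining
    freedom absorbed into alpha.
    """
    r = _validate_rotation(r, tol=tol)
    sb = float(np.clip(r[0, 2], -1.0, 1.0))
    beta = math.asin(sb)
    if abs(sb) > 1.0 - 1e-12:  # gimbal lock: alpha and gamma degenerate
        gamma = 0.0
        alpha = math.atan2(r[1, 0], r[1, 1])
        if sb < 0:
            alpha = -alpha
    else:
        alpha = math.atan2(-r[1, 2], r[2, 2])
        gamma = math.atan2(-r[0, 1], r[0, 0])
    return EulerAngles(alpha, beta, gamma)


def apply_transform(transform: SimilarityTransform, points: PointSet) -> PointSet:
    """Map every point of ``points`` through ``transform``; labels preserved."""
    return PointSet(points.labels, transform.apply(points.coords))


def registration_residual(
    pre: PointSet, post: PointSet, transform: SimilarityTransform
) -> tuple[float, np.ndarray, float]:
    """Fiducial registration error of ``transform`` on a correspondence pair.

    Returns ``(residual_e, per_point_residuals, sum_squared_residuals)`` where
    ``per_point_residuals[i] = || post_i - (s r pre_i + t) ||`` and
    ``residual_e`` is their root mean square.
    """
    if len(pre) != len(post):
        raise CorrespondenceError(
            f"point sets differ in length ({len(pre)} vs {len(post)})"
        )
    delta = post.coords - transform.apply(pre.coords)
    per_point = np.linalg.norm(delta, axis=1)
    ss = float(np.sum(per_point**2))
    return float(np.sqrt(ss / len(pre))), per_point, ss


def _quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def horn_register(
    pre: PointSet,
    post: PointSet,
    with_scale: bool = True,
    scale_method: str = "lsq",
) -> RegistrationResult:
    """Closed-form least-squares similarity registration (unit quaternions).

    Finds the transform minimising ``sum_i || post_i - (s r pre_i + t) ||^2``:

    1. subtract each set's centroid;
    2. accumulate the 3x3 cross-covariance ``S = sum_i pre'_i post'_i^T``;
    3. assemble the symmetric 4x4 quaternion matrix ``N`` from ``S``;
    4. the unit eigenvector of N's largest eigenvalue is the optimal rotation
       quaternion;
    5. estimate the scale (see ``scale_method``), or fix ``s = 1`` when
       ``with_scale`` is false;
    6. ``t = centroid(post) - s r centroid(pre)``.

    Parameters
    ----------
    pre, post
        Corresponding point sets (label order defines correspondence),
        each with at least three non-collinear points.
    with_scale
        Fit the isotropic scale factor; with ``False`` the transform is rigid
        (``s = 1`` exactly).
    scale_method
        ``"lsq"`` (default): ``s = sum_i post'_i . (r pre'_i) / sum||pre'||^2``,
        the exact minimiser of the one-sided objective above.  ``"symmetric"``:
        ``s = sqrt(sum||post'||^2 / sum||pre'||^2)``, independent of the
        rotation and symmetric under exchanging the two scans at the cost of
        a marginally larger one-sided residual.  Identical on noiseless data;
        for same-scanner pre/post pairs both sit at s ~ 1.
    """
    if scale_method not in ("lsq", "symmetric"):
        raise ValueError(f"unknown scale_method {scale_method!r}")
    if len(pre) != len(post):
        raise CorrespondenceError(
            f"point sets differ in length ({len(pre)} vs {len(post)})"
        )
    n = len(pre)
    if n < 3:
        raise UnderdeterminedError(
            "at least three fiducial pairs (nine constraints) are required; "
            f"got {n}"
        )
    c_pre = pre.coords.mean(axis=0)
    c_post = post.coords.mean(axis=0)
    p = pre.coords - c_pre
    q = post.coords - c_post

    sv = np.linalg.svd(p, compute_uv=False)
    if sv[1] < COLLINEARITY_RTOL * sv[0]:
        raise DegenerateGeometryError(
            "fiducials are (near-)collinear; rotation about the line is "
            "unconstrained"
        )

    s_mat = p.T @ q
    sxx, sxy, sxz = s_mat[0]
    syx, syy, syz = s_mat[1]
    szx, szy, szz = s_mat[2]
    n_mat = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, syy - sxx - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, szz - sxx - syy],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(n_mat)
    quat = eigvecs[:, np.argmax(eigvals)]
    # Canonical sign: scalar part non-negative; ties broken toward the first
    # non-zero component positive.
    if quat[0] < 0:
        quat = -quat
    elif quat[0] == 0:
        nz = np.flatnonzero(quat)
        if nz.size and quat[nz[0]] < 0:
            quat = -quat
    rotation = _quaternion_to_matrix(quat / np.linalg.norm(quat))

    if not with_scale:
        scale = 1.0
    elif scale_method == "symmetric":
        scale = float(np.sqrt(np.sum(q**2) / np.sum(p**2)))
    else:
        scale = float(np.trace(rotation @ s_mat) / np.sum(p**2))
        if scale <= 0:
            raise DegenerateGeometryError(
                "least-squares scale is non-positive; the point sets do not "
                "support a similarity registration"
            )
    translation = c_post - scale * rotation @ c_pre

    transform = SimilarityTransform(rotation, translation, scale)
    residual_e, per_point, ss = registration_residual(pre, post, transform)
    return RegistrationResult(transform, per_point, residual_e, ss)
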