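"""Shared fixtures and independent oracles.

The oracles deliberately avoid the package's own code paths: rotations come
from scipy's Rotation class, the iterative registration oracle minimises the
same objective by multi-start nonlinear least squares over explicit
(angles, translation, scale) parameters, and the Kabsch-style reference
registration uses scipy's align_vectors.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from stereoreg import fiducial_arc
from stereoreg.registration import PointSet


@pytest.fixture(scope="session")
def arc() -> PointSet:
    return fiducial_arc()


def multistart_lsq_sse(
    pre: np.ndarray,
    post: np.ndarray,
    n_starts: int = 20,
    seed: int = 0,
    with_scale: bool = True,
) -> float:
    """Best sum of squared residuals from iterative least squares over
    (alpha, beta, gamma, t, s) started from ``n_starts`` random points."""
    rng = np.random.default_rng(seed)
    t0 = post.mean(axis=0) - pre.mean(axis=0)

    def residuals(params: np.ndarray) -> np.ndarray:
        rot = Rotation.from_euler("XYZ", params[:3]).as_matrix()
        t = params[3:6]
        s = params[6] if with_scale else 1.0
        return (post - (s * pre @ rot.T + t)).ravel()

    best = np.inf
    for _ in range(n_starts):
        x0 = np.concatenate(
            [
                rng.uniform(-np.pi, np.pi, 3),
                t0 + rng.normal(0, 5, 3),
                [rng.uniform(0.8, 1.2)],
            ]
        )
        fit = least_squares(residuals, x0, method="lm")
        sse = 2.0 * fit.cost
        best = min(best, sse)
    return float(best)


def kabsch_register(
    pre: np.ndarray, post: np.ndarray, with_scale: bool = True
) -> tuple[np.ndarray, np.ndarray, float]:
    """Reference similarity registration via scipy's align_vectors
    (SVD/Kabsch route, independent of the quaternion implementation)."""
    c_pre = pre.mean(axis=0)
    c_post = post.mean(axis=0)
    p = pre - c_pre
    q = post - c_post
    rot, _ = Rotation.align_vectors(q, p)
    r = rot.as_matrix()
    s = (
        float(np.einsum("ij,ij->", q, p @ r.T) / (p**2).sum())
        if with_scale
        else 1.0
    )
    t = c_post - s * r @ c_pre
    return r, t, s
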