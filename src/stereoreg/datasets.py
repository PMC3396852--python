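"""Bundled reference data from the six-pig bilateral putamen implantation study.

Two small tables are shipped as code: the nine-fiducial arc geometry (sagittal
coordinates relative to fiducial 5, coronal relative to the back of the arc,
axial relative to its base, all mm) and the per-subject targeting outcomes —
planned target coordinates with per-axis error magnitudes for both
hemispheres, from which the per-hemisphere Euclidean errors and the cohort
mean of 0.623 mm (SD 0.33 mm) are recomputed, never stored.
"""

from __future__ import annotations

import numpy as np

from .accuracy import AccuracyRecord, CohortSummary, TargetPlan, cohort_summary, target_error
from .registration import Point3, PointSet

__all__ = [
    "fiducial_arc",
    "study_target_plans",
    "study_axis_errors",
    "study_accuracy_records",
    "study_cohort",
]

# Arc-frame fiducial coordinates (mm); fiducial 5 defines sagittal zero.
_ARC = {
    "1": (-72.0, 99.0, 87.0),
    "2": (-60.0, 87.0, 104.0),
    "3": (-36.0, 111.0, 104.0),
    "4": (-24.0, 123.0, 77.0),
    "5": (0.0, 135.0, 87.0),
    "6": (24.0, 111.0, 104.0),
    "7": (36.0, 123.0, 77.0),
    "8": (60.0, 87.0, 87.0),
    "9": (60.0, 75.0, 104.0),
}

# (subject, side) -> planned target (x, y, z mm) and per-axis absolute
# positional errors (|dx|, |dy|, |dz| mm) as measured between the mapped plan
# and the infusion centre.
_STUDY = {
    ("MA26", "RHS"): ((111.4, 136.9, 27.2), (0.5, 0.7, 0.5)),
    ("MA26", "LHS"): ((89.9, 137.0, 27.2), (0.1, 0.7, 0.5)),
    ("MA27", "RHS"): ((87.4, 157.7, 26.5), (0.1, 0.1, 0.8)),
    ("MA27", "LHS"): ((112.4, 157.3, 26.4), (0.1, 0.1, 0.1)),
    ("V3", "RHS"): ((107.5, 124.5, 46.7), (0.25, 0.5, 0.25)),
    ("V3", "LHS"): ((84.8, 132.7, 48.7), (0.25, 0.5, 0.1)),
    ("Thursday", "RHS"): ((111.9, 121.2, 46.3), (0.25, 0.7, 0.8)),
    ("Thursday", "LHS"): ((91.7, 119.8, 45.6), (0.1, 0.0, 0.0)),
    ("ZR1", "RHS"): ((88.9, 126.9, 31.3), (0.1, 0.1, 0.2)),
    ("ZR1", "LHS"): ((112.0, 127.2, 31.3), (0.3, 0.25, 0.1)),
    ("ZR3", "RHS"): ((112.4, 164.1, 27.2), (0.3, 0.5, 0.5)),
    ("ZR3", "LHS"): ((89.7, 163.4, 27.2), (0.3, 0.8, 0.1)),
}


def fiducial_arc() -> PointSet:
    """The nine-fiducial arc geometry, labelled "1".."9"."""
    labels = tuple(_ARC)
    coords = np.array([_ARC[l] for l in labels])
    return PointSet(labels, coords)


def study_target_plans() -> list[TargetPlan]:
    """Planned bilateral putamen targets for the six study subjects."""
    return [
        TargetPlan(subject, side, Point3(*planned))
        for (subject, side), (planned, _) in _STUDY.items()
    ]


def study_axis_errors() -> dict[tuple[str, str], tuple[float, float, float]]:
    """Measured per-axis error magnitudes keyed by (subject_id, side)."""
    return {key: errs for key, (_, errs) in _STUDY.items()}


def study_accuracy_records() -> list[AccuracyRecord]:
    """Per-hemisphere accuracy records with Euclidean errors recomputed from
    the per-axis measurements (tip reconstructed as plan + error vector)."""
    records = []
    for (subject, side), (planned, errs) in _STUDY.items():
        plan = Point3(*planned)
        tip = Point3(*(np.asarray(planned) + np.asarray(errs)))
        records.append(target_error(plan, tip, subject_id=subject, side=side))
    return records


def study_cohort() -> CohortSummary:
    """Cohort summary of the twelve implantations (mean 0.623 mm, SD 0.33)."""
    return cohort_summary(study_accuracy_records())
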