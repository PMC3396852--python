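# Methods

## Problem

In MRI-guided stereotactic implantation, a fiducial arc of nine spheres rigidly
attached to the head frame is imaged in both the pre-operative (planning) and
post-operative (verification) scans. Targeting accuracy is quantified by
(1) co-registering the two scan spaces from the fiducial coordinates,
(2) mapping each planned target into post-operative space, and
(3) measuring its distance to the implanted cannula tip, visible as a small
hypointense volume at the centre of the contrast infusion.

## Registration model

Given corresponding pre- and post-operative fiducial coordinates
F1 = {p_i} and F2 = {q_i} (mm), the pipeline fits the similarity transform

    q_i ≈ s · r · p_i + t

by minimising the summed squared residuals Σ_i ‖q_i − (s r p_i + t)‖².
The solver is the closed-form unit-quaternion solution to the absolute
orientation problem: after centroid subtraction, the 3×3 cross-covariance
S = Σ p'_i q'_iᵀ is folded into the symmetric 4×4 quaternion matrix N, and the
eigenvector of N's largest eigenvalue is the optimal rotation quaternion. No
iteration, no initial guess, global optimum in one step. The quaternion sign
is canonicalised (non-negative scalar part; ties broken toward the first
non-zero component positive).

**Scale.** Two closed-form scale estimators are provided:

- `"lsq"` (default): s = Σ q'_i·(r p'_i) / Σ‖p'_i‖², the exact minimiser of
  the one-sided objective above. This is the default because it is the only
  estimator consistent with the stated least-squares objective — with it the
  closed form never loses to an iterative multi-start refinement (a property
  the test suite checks on noisy ensembles).
- `"symmetric"`: s = sqrt(Σ‖q'‖² / Σ‖p'‖²), independent of the rotation and
  symmetric under swapping the scans, at the cost of a marginally larger
  one-sided residual under noise.

The two agree exactly on noiseless data, and for same-scanner pre/post pairs
both sit at s ≈ 1; `with_scale=False` forces a rigid fit with s = 1 exactly.

**Residual statistic.** The fiducial registration error is reported two ways:
`residual_e`, the root-mean-square per-fiducial residual (an *average*
re-positional error, invariant to fiducial count), and
`sum_squared_residuals`, the raw e² = Σ Δx²+Δy²+Δz². RMS is the primary
statistic because "average error" is only meaningful per fiducial.

**Degeneracy.** Fewer than three point pairs is refused (nine coordinate
constraints are the minimum that determines the transform); a centered
pre-set whose second singular value is below 1e-6 of the largest is refused
as collinear (rotation about the line is unconstrained). Returned rotations
satisfy ‖rᵀr − I‖∞ < 1e-9 and det r = 1 ± 1e-9.

**Euler convention.** For reporting, rotations compose intrinsically as
r = Rx(α)·Ry(β)·Rz(γ). The inverse (`decompose_rotation`) reproduces r to
1e-9 away from gimbal lock; at |β| = π/2 the remaining one-parameter freedom
is resolved by setting γ = 0.

## Target accuracy

A planned target is mapped through the fitted transform; the error vector is
tip − planned (post-op space) with Euclidean norm √(Δx²+Δy²+Δz²). Cohort
statistics follow the arithmetic of the published study table: per-record
Euclidean errors are rounded to 2 d.p. *before* averaging (the published
0.623 mm mean is the mean of the rounded column; the unrounded mean is
0.625 mm), and the SD uses the sample (n−1) denominator, the only choice
consistent with the published 0.33. Unrounded summaries are exposed under
`mean_unrounded` / `sd_unrounded`. Published per-axis errors are magnitudes,
so rendered table cells use absolute deltas; n = 1 cohorts report SD as
`NA`, never 0.

## Volume localization

Volumes are axis-aligned voxel grids with anisotropic spacing (default
0.575 × 0.575 × 0.8 mm, the acquisition protocol's voxel size) and a
voxel-centre, 0-based world convention: world = origin + index ⊙ spacing.

- **Fiducial spheres** (bright): voxels above a user threshold are grouped by
  26-connectivity; components under 3 voxels are rejected as speckle; each
  component yields an intensity-weighted centroid with weights taken relative
  to the volume minimum. Background-relative weighting makes the centroid
  exactly invariant to a constant sub-threshold pedestal and lets the weights
  track the in-sphere volume fraction, which is what partial voluming encodes
  — this is how sub-voxel accuracy (≲0.01 mm on the default grid) is
  recovered from "slightly oval"-looking spheres. The `expected_count`
  brightest components are returned.
- **Cannula tip** (dark): within a spherical ROI, intensities are split by
  Otsu's threshold; the largest 26-connected component of the darker class is
  the tip, and its *unweighted* geometric centroid is returned — the tip
  location is defined as the centre of the hypointense volume, so no
  weighting is warranted.
- **Correspondence**: detections are matched to the reference arc by
  Hungarian assignment on squared distances after centroid alignment; any
  matched pair farther than 10 mm (configurable) is treated as ambiguous.
  The arc's minimum inter-fiducial spacing (~17 mm) dwarfs realistic
  localization noise, so matching is essentially error-free at σ ≤ 0.5 mm.

## Synthetic data

No imaging data accompanies the study, so the generator emulates it:

- **Scan pairs**: the nine-fiducial arc observed twice — once directly, once
  under a known similarity motion — with i.i.d. per-axis Gaussian
  localization noise on every fiducial (default σ = 0.1 mm, chosen so that
  simulated repositioning-trial mean residuals land in the ~0.1–0.2 mm regime
  of the study's measured 0.16 mm average re-positional error; an anisotropic
  per-axis σ is available for the coarser 0.8 mm axis). The noise model is a
  stand-in: the real error mixes scanner, repositioning-hardware and
  software-localization components that cannot be separated from published
  numbers.
- **Volumes**: spheres are rasterized with each voxel's intensity
  proportional to the fraction of the voxel inside the sphere, estimated by a
  fixed 3×3×3 subvoxel sampling — deterministic, cheap, and accurate to a few
  percent in integrated volume, which is adequate at the pipeline's 0.1 mm
  test tolerances. On the anisotropic default grid this reproduces the
  partial-volume oval appearance.
- **Tips**: planned target plus i.i.d. per-axis Gaussian displacement
  (default σ = 0.39 mm, calibrated so the expected Euclidean error
  σ√(8/π) equals the study cohort's observed 0.62 mm mean).
- **Infusion**: the stepped convection-enhanced-delivery ramp is bookkept as
  Σ rate × duration (the study regime totals 120 µl). No transport or MR
  physics is modelled.

All stochastic generators are pure functions of (inputs, seed).

What passing synthetic tests do *not* show: robustness to bias fields,
motion artefact, non-Gaussian localization error, or mis-detected/missing
fiducials in real scans; the published software's proprietary search routine
is unspecified, so only self-consistency on synthetic volumes is testable.

## Problem sizes and numerical choices

Monte-Carlo checks use 500-trial registration ensembles (noise-scaling
ratio), 1000-trial matching sweeps, and 10⁴ tip draws against the
chi-distribution closed form — sizes at which the checked statistics are
stable to well under their tolerances while the full suite runs in seconds.
The iterative least-squares oracle used to certify optimality runs from 10–20
random starts per instance. Machine outputs (CSV/JSON) keep full double
precision; display rounding (1 d.p. coordinates, 2 d.p. errors) is applied
only when rendering reports.

## Known limitations

- Registration assumes label-order correspondence and equal, isotropic point
  weights; no ICP, no deformable registration, no outlier rejection.
- Volume I/O supports axis-aligned NIfTI only; oblique acquisitions are
  refused rather than resampled.
- The tip localizer assumes exactly one dominant hypointense component in the
  ROI; overlapping hypointensities (e.g. haemorrhage) would be conflated.
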