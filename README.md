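# stereoreg

Fiducial-based MRI co-registration and stereotactic targeting-accuracy
analysis, built around the workflow used to verify cannula implantation into
the putamen of large animal models: a nine-sphere fiducial arc is imaged in
pre- and post-operative T1 scans, the two scan spaces are co-registered from
the fiducial coordinates, and the distance between each planned target
(mapped into post-operative space) and the implanted cannula tip quantifies
targeting accuracy per hemisphere.

For neurosurgery-methods researchers and imaging scientists who need the
full chain — fiducial detection in volumes, point-set registration, target
registration error statistics — or any piece of it.

## The core computation

Given corresponding fiducial sets F1 (pre-op) and F2 (post-op), the package
fits the similarity transform

    F2 = s · r · F1 + t

minimising Σᵢ ‖q_i − (s r p_i + t)‖² in closed form via Horn's
unit-quaternion solution (no iteration, global optimum). The fiducial
registration error e is reported as the RMS per-fiducial residual alongside
the raw e² = Σ Δx²+Δy²+Δz². Planned targets are mapped through the fitted
transform and compared with measured tip positions: per-axis deltas
(x sagittal, y coronal, z axial) and the Euclidean distance, summarised over
a cohort as mean ± sample SD. See `docs/methods.md` for the model, the scale
estimators, and the localization algorithms.

## Worked example

```python
import numpy as np
from stereoreg import (
    fiducial_arc, simulate_scan_pair, SimulationConfig, EulerAngles,
    horn_register, map_planned_target, target_error, cohort_summary,
    TargetPlan, Point3, study_cohort,
)

# simulate a pre/post scan pair: 3 deg rotation about the axial axis,
# a small table shift, 0.1 mm fiducial localization noise
cfg = SimulationConfig(EulerAngles(0, 0, np.radians(3)), (2.0, -1.0, 0.5),
                       noise_sd=0.1, seed=42)
f1, f2, truth = simulate_scan_pair(fiducial_arc(), cfg)
res = horn_register(f1, f2)
print(f"residual_e = {res.residual_e:.3f} mm, scale = {res.transform.scale:.5f}")

# map a planned target and score it against a measured tip
plan = TargetPlan("demo", "RHS", Point3(111.4, 136.9, 27.2))
planned_postop = map_planned_target(res.transform, plan)
tip = Point3.from_array(planned_postop.as_array() + [0.5, 0.7, 0.5])
rec = target_error(planned_postop, tip, "demo", "RHS")
print(f"euclidean error = {rec.euclidean:.2f} mm")

# the bundled six-subject bilateral implantation cohort
c = study_cohort()
print(f"cohort: n={c.n}, mean={c.mean_euclidean:.3f} mm, sd={c.sd_euclidean:.2f} mm")
```

prints

```
residual_e = 0.150 mm, scale = 1.00045
euclidean error = 0.99 mm
cohort: n=12, mean=0.623 mm, sd=0.33 mm
```

`residual_e` is the RMS fiducial misfit after optimal registration (with two
independently noisy observations of nine fiducials at σ = 0.1 mm, residuals
of one to two tenths of a millimetre are expected); the 0.99 mm record is the Euclidean targeting error implied by
per-axis errors of 0.5, 0.7, 0.5 mm; and the bundled cohort reproduces the
published mean Euclidean implantation error of 0.623 mm (SD 0.33 mm).

A command-line interface wraps the same pipeline:

```bash
stereoreg simulate --seed 42 --output-dir sim/
stereoreg register sim/f1.csv sim/f2.csv --out-json transform.json
stereoreg evaluate plans.csv tips.csv --transform-json transform.json --out-report report.csv
stereoreg localize volume.nii.gz --threshold 50 --out-csv detections.csv
```

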