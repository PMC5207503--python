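# vbsalab

A virtual depth-camera laboratory for estimating **whole-body surface area
(WBSA)** from a single camera view.

WBSA is a key dosing and diagnostic quantity in clinical practice (burn
assessment, chemotherapy dosing, metabolic scaling), yet it is essentially
never measured — it is guessed from height and weight with century-old
formulae such as Du Bois' `WBSA = 0.007184 · W^0.425 · H^0.725`. A cheap
depth camera sees only one side of a patient: the **view body surface area
(VBSA)**. This package provides everything needed to study — entirely *in
silico*, with exact ground truth — how well WBSA can be predicted from VBSA
as a function of where the camera stands:

* **`body_synth`** — parametric synthetic humanoids (stature, girth,
  muscle/fat balance, gender-shape blend) with exact mesh WBSA, NHANES-style
  measurement tables, and two population schemes: i.i.d.-uniform "random"
  populations rich in extreme bodies, and base-subjects-plus-k-variations
  families that vary only girth and muscle/fat.
* **`mesh_core`** — triangle meshes with stable per-triangle IDs, OBJ I/O,
  `A = ½|u × v|` triangle areas, flat midpoint subdivision.
* **`camera`** — a pinhole depth camera: intrinsics `K`, polar placement
  (azimuth θ, elevation φ, distance D), one ray per pixel center,
  nearest-intersection ray casting that harvests the **visible-triangle-ID
  list**, plus a Kinect-like axial/lateral noise model. The framing relation
  `maxStature = 2 tan(ψ) D` (ψ = half vertical FOV) sets the default
  distance of 4.3 m.
* **`visibility`** — VBSA three ways: ground truth (sum of original-mesh
  areas over visible IDs), degraded by Bernoulli hole simulation, and
  re-measured from a surface meshed directly on the organized point cloud.
* **`regression`** — per-angle linear models `WBSA = c₁·VBSA + c₀`
  (optionally `+ c₂·stature + …`), 10-fold cross-validated RMSE/MSPE/MAPE,
  Spearman correlation matrices, grouped fits, residual diagnostics.
* **`experiment`** / CLI — the full sweep over the angle grid
  θ ∈ {0°, 30°, 45°, 60°, 90°, 120°, 135°, 150°, 180°},
  φ ∈ {0°, ±30°, ±45°, ±60°, ±90°} (poles at θ = 0 only).

## Worked example

```python
import numpy as np
from vbsalab import (BodyParams, make_body, total_area, measure_subject,
                     default_intrinsics, CameraPlacement, raycast,
                     vbsa_ground_truth, sample_random_population,
                     cross_validate, du_bois)

params = BodyParams(stature=175, girth=1.0, muscle_fat=0.5, gender_shape=0.3)
body = make_body(params)
wbsa = total_area(body).wbsa
meas = measure_subject(body, params)
print(f"WBSA = {wbsa:.1f} dm^2, weight proxy = {meas['weight_kg']:.1f} kg")
print(f"Du Bois estimate = {du_bois(meas['weight_kg'], 175):.2f} m^2")

intr = default_intrinsics()  # 640x480, 43 deg vertical FOV
for theta in (0, 60, 90):
    res = raycast(body, intr, CameraPlacement(theta=theta, distance=43.0))
    v = vbsa_ground_truth(body, res)
    print(f"theta={theta:3d}: VBSA = {v:6.1f} dm^2  ({100*v/wbsa:.0f}% of WBSA)")

records, meshes = sample_random_population(100, seed=42)
wb = np.array([r.wbsa for r in records])
for theta in (0, 90):
    vb = np.array([vbsa_ground_truth(m, raycast(m, default_intrinsics(320,240),
                    CameraPlacement(theta=theta))) for m in meshes])
    fit = cross_validate(vb, wb, k=10, seed=0)
    print(f"theta={theta:3d}: WBSA = {fit.coefficients['c1']:.3f}*VBSA + "
          f"{fit.coefficients['c0']:.2f},  CV RMSE = {fit.cv_rmse:.2f} dm^2, "
          f"CV MAPE = {fit.cv_mape:.2f}%")
```

prints

```
WBSA = 195.6 dm^2, weight proxy = 64.4 kg
Du Bois estimate = 1.78 m^2
theta=  0: VBSA =   77.9 dm^2  (40% of WBSA)
theta= 60: VBSA =   68.9 dm^2  (35% of WBSA)
theta= 90: VBSA =   50.1 dm^2  (26% of WBSA)
theta=  0: WBSA = 2.556*VBSA + 24.07,  CV RMSE = 4.91 dm^2, CV MAPE = 1.76%
theta= 90: WBSA = 4.266*VBSA + 21.07,  CV RMSE = 11.85 dm^2, CV MAPE = 4.62%
```

The frontal view (θ = 0°) exposes the most surface, so its linear
coefficient c₁ is smallest and the prediction error lowest; side-on
(θ = 90°) the camera sees the least area and prediction degrades — the
central angle-dependence the laboratory is built to quantify.

The same pipeline is scriptable from the shell:

```bash
vbsalab generate-population --kind random --n 200 --seed 1 --out pop/
vbsalab render pop/meshes/rand00000.obj --theta 30 --out view/
vbsalab sweep --population pop/ --out sweep/
vbsalab report --fits-csv sweep/angle_fits.csv --out report/
```

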