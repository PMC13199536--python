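# vfr — vertebral FE reproducibility

`vfr` implements, end to end and on fully synthetic ground truth, the
pipeline used to quantify how operator-dependent image segmentation
propagates into CT-based subject-specific finite-element (FE) predictions
of vertebral mechanics — for metastatic (lytic) as well as intact
vertebrae. It is aimed at researchers in computational biomechanics and
medical image analysis who want a reproducible, dependency-light testbed
for segmentation-to-strength sensitivity studies.

The package covers seven stages:

1. **Synthetic data** — analytic vertebra phantoms (elliptic-cylinder body,
   optional lytic lesions), a virtual QCT scanner with a five-rod
   calibration phantom (BMD 0.00–0.20 g/cm³, 15 mm rods, 0.60 mm voxels),
   and simulated operators that perturb the true mask in signed-distance
   space (global bias, correlated surface jitter, per-slice jitter,
   Bernoulli inclusion of an osteophyte-like feature).
2. **Densitometric calibration** — OLS of rod BMD on mean HU in 7.5 mm
   square prismatic ROIs; voxelwise HU→ρ_QCT conversion per scan.
3. **Mask metrics** — RVD, Dice, mean surface distance and exact Hausdorff
   distance between boundary voxel centres; 3 mm binary median smoothing;
   mean CSA with endplate bands excluded; three-comparison intra/inter
   summaries.
4. **Model building** — structured TET10 meshing (Kuhn 6-tet split of
   1 mm cubes, shared midside nodes), landmark-based anatomical alignment,
   endplate node sets, body height Hm, per-element density sampling and
   the trabecular power laws
   ρ_QCT = ρ_ash = 0.6 ρ_app, E = 4730 ρ_app^1.56 MPa,
   σ_y1 = 21.7 ρ_app^1.52 MPa, E_py = 0.05 E.
5. **FE solver** — small-strain J2 (von Mises) plasticity with linear
   isotropic hardening (radial return, consistent tangent), Newton with
   line search, displacement-controlled compression to 1.9% apparent
   strain, nodal principal strains ε_p1, ε_p3.
6. **Mechanical metrics** — F_U (axial reaction at 1.9% apparent strain),
   σ_U = F_U/CSA, K (slope of the linear range), E_APP = K·Hm/CSA,
   mid-height strain frequency tables, 27 spherical probes of 2 mm radius.
7. **Precision statistics** — per-vertebra CV = SD/m, across-vertebrae
   PE = √(Σ CV_j²/n), pairwise ARD = |A−B|/mean·100, paired t-tests with
   normality/equal-variance flags, and exploratory SD(geometric) vs
   CV(mechanical) regressions.

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.

## Worked example

```python
from vfr import (PhantomGeometry, ScannerModel, make_vertebra_phantom,
                 render_qct, DensitometricCalibration, build_fe_model,
                 solve_compression, mechanical_summary)
from vfr.mask_metrics import pairwise_geometric_summary
from vfr.operators import INTRA_PRESET, simulate_operator_mask

geom = PhantomGeometry(a=10.0, b=8.0, height=16.0, waist=0.15)
scanner = ScannerModel(noise_sd=10.0, psf_sd_mm=0.4)
phantom = make_vertebra_phantom(geom, spacing=0.6,
                                rod_zone_mm=scanner.rod_zone_mm,
                                min_grid_xy_mm=scanner.rod_row_extent + 10)

qct = render_qct(phantom, scanner, seed=7)            # HU volume with rods
cal = DensitometricCalibration().fit(qct)             # five-rod OLS
bmd = cal.transform(qct)                              # g/cm3 volume

masks = [simulate_operator_mask(phantom, INTRA_PRESET, seed=s)
         for s in (1, 2, 3)]                          # 3 repeat segmentations
rep = pairwise_geometric_summary(masks, "intra")

model = build_fe_model(bmd, masks[0], elem_size=2.5)
result = solve_compression(model, n_increments=4)     # to 1.9% app. strain
print(mechanical_summary(result, model).as_dict())
```

Output of this exact script (values are deterministic given the seeds):

```
calibration: slope=0.001001 g/cm3 per HU, intercept=0.0149 g/cm3, R2=1.00000
intra agreement: DC=0.9410  RVD=10.65%  MSD=0.345 mm  HD=1.15 mm
model: 1242 TET10 elements, Hm=15.00 mm, CSA=206.2 mm2, BMC=0.440 g
F_U=575.5 N  sigma_U=2.791 MPa  K=6395 N/mm  E_APP=465.2 MPa
```

Reading the numbers: the fitted calibration inverts the scanner's affine
HU map (slope ≈ 1/1000, R² = 1 up to noise); the three repeat
segmentations of one simulated operator agree to Dice 0.94 with
sub-voxel mean surface distance; the 1.9%-apparent-strain compression of
the first segmentation's model carries 575 N at an apparent stress of
2.8 MPa, and the normalised apparent modulus E_APP sits in the hundreds
of MPa, as expected for trabecular bone at ρ_app ≈ 0.25 g/cm³. The RVD
of ~10% reflects one repeat drawing a 2-sigma global bias — volume is the
most quantisation-sensitive of the four agreement metrics on a small
body.

A full study (each vertebra: three intra-operator repeats plus two other
operators, geometric tables, mechanical CV/PE/ARD, t-tests and
regressions) runs from one config:

```bash
vfr run-all --seed 0 --out runs/demo        # defaults: 3 control + 3 lytic
vfr synth --seed 0 --out study/             # just the synthetic inputs
vfr calibrate --qct scan.nii.gz --rods rods.json --out bmd.nii.gz
vfr maskmetrics --a op1.nii.gz --b op2.nii.gz --out metrics.csv
vfr solve --bmd bmd.nii.gz --mask op1.nii.gz --out model1
```

Note that `run-all` at the full default problem size (0.60 mm voxels,
1 mm elements, ~150k elements per model, 30 models) is an overnight job
on one CPU with the bundled sparse direct solver; the statistical suites
in `tests/` use scaled-down bodies and 2–3 mm elements instead (a few
seconds per model), which preserve every planted effect being tested.

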