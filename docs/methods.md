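# Methods

`vfr` reconstructs, on fully synthetic ground truth, the workflow used to
ask how much operator-dependent image segmentation propagates into
subject-specific finite-element (FE) predictions of vertebral mechanics:
segment a vertebra from quantitative CT (QCT), build a density-calibrated
elasto-plastic FE model, compress it, and compare geometric and mechanical
outcomes across repeated segmentations. Because clinical QCT with repeated
manual segmentations cannot be shared, every stage here runs against an
analytic phantom whose geometry, density and landmarks are known exactly —
so each stage is verifiable against a closed form or a brute-force oracle.

## Synthetic ground truth

**Vertebra phantom.** The vertebral body is an elliptic cylinder (semi-axes
`a`, `b`, height `h`, defaults 20 x 15 x 30 mm) with a cosine waist
`s(t) = 1 - w sin^2(pi t)` so both end cross-sections are full ellipses.
Trabecular density is uniform `rho_QCT = 0.15 g/cm^3` (mid-range for
vertebral trabecular bone on a QCT scale that tops out at the densest
0.20 g/cm^3 calibration rod). Lytic lesions are ellipsoids strictly inside
the body whose density is multiplied by a factor in [0, 1). Ground truth
available analytically: the voxelised mask, density field, body height
`Hm = h`, mean cross-sectional area (CSA) with 10% endplate bands
excluded, mineral content (BMC), and six landmarks (most anterior point
and the two posterior corners of each end cross-section, at +/-120 deg
from anterior). Posterior elements are deliberately not modelled: the
mechanical analysis keys on the vertebral body, and whole-vertebra scope
only changes which mask is compared, not the mechanics.

**Scanner.** `HU = a_s * rho + b_s` (defaults 1000 HU per g/cm^3, -15 HU),
optional Gaussian PSF blur and additive Gaussian noise, 0.60 mm isotropic
voxels, and an in-line calibration phantom of five cylindrical rods
(15 mm diameter; equivalent BMD 0.00/0.05/0.10/0.15/0.20 g/cm^3). With
zero noise and blur the affine law holds exactly at every voxel, which is
what makes the calibration round-trip testable to 1e-10.

**Simulated operators.** A manual segmentation differs from truth through
four mechanisms, all additive in the signed-distance field of the true
mask (threshold form `{x : d(x) <= T(x)}`, amplitudes in mm):

1. a global erode/dilate bias drawn once per mask (SD `offset_sd`);
2. a smooth correlated boundary displacement (unit-variance Gaussian
   random field, correlation length ~6-8 mm, scaled by `jitter_amp`) —
   the "interpretation" component;
3. an independent per-transverse-slice offset (`slice_amp`), mimicking the
   slice-by-slice contouring workflow;
4. Bernoulli inclusion of an ambiguous half-ellipsoid surface feature (an
   osteophyte-like bump on the anterior equator), the mechanism behind
   occasional large inter-operator Hausdorff distances.

The signed distance is shifted half a voxel toward the boundary so its
zero level sits on the actual surface; without this, voxel-centre distance
transforms quantise at one voxel and sub-voxel amplitudes would change
nothing. Masks are reduced to their largest connected component. With all
amplitudes zero the output equals the true mask bit-for-bit.

Preset amplitudes (intra: 0.10/0.15/0.10 mm, no inclusion; inter:
0.25/0.35/0.20 mm, inclusion probability 0.25) are calibration knobs
chosen once so that intra-operator agreement exceeds inter-operator
agreement with Dice values in the high-0.9 range at 0.6 mm voxels — the
qualitative regime of published manual-segmentation studies. They are not
estimates of any particular operator population, so passing tests support
the *machinery* (metrics, propagation, statistics), not quantitative
claims about real operators. Real manual segmentation also exhibits
structured anatomical confusions (transverse-process boundaries, endplate
partial volume) that this additive model does not emulate.

**Study design and seeding.** A study of `n_control + n_lytic` vertebrae
gives each vertebra five masks: three repeats by Operator 1 (intra set)
and one each by Operators 2 and 3; the inter set is Operator 1's first
repeat plus Operators 2 and 3, compared pairwise in both modes as the
three comparisons (1v2, 1v3, 2v3). All randomness flows from one master
seed via `SeedSequence(master, spawn_key=(vertebra, slot))`, so any
artefact regenerates in isolation from the manifest.

## Calibration

Ordinary least squares of known rod BMD on mean HU measured in square
prismatic ROIs (side = half the rod diameter, i.e. 7.5 mm at protocol
size) centred on each rod axis over the rod's full axial extent in the
field of view. The regression direction is BMD-on-HU, matching its use as
a conversion; each scan is calibrated individually. Calibrated densities
below 0 g/cm^3 are clamped to zero: negative density is unphysical and
the material power laws are undefined there. Exposed as a fit/transform
estimator (`DensitometricCalibration`) because the stage genuinely has
that shape.

## Geometric agreement metrics

RVD `|V_A - V_B| / V_B` (asymmetric; the second argument is the
reference), Dice `2|A∩B| / (|A|+|B|)`, mean surface distance (symmetric
average of the two directed mean nearest-neighbour distances) and exact
max-form Hausdorff distance (not HD95). Distances are Euclidean between
boundary *voxel centres* (face-adjacent background neighbour definition;
volume-border voxels count as boundary) — not sub-voxel mesh surfaces —
computed with k-d trees and verified against an O(n^2) brute force to
1e-9 mm. Masks are median-smoothed (3 mm cubic window, width forced odd;
binary median = majority vote) before comparison by default, matching the
pipeline order; a flag disables it. CSA drops a configurable 10% band of
occupied slices at each end as the endplates — the protocol excludes
endplates but does not state the extent.

## FE model construction

**Meshing.** Structured decomposition: the mask is resampled to cubes of
edge `elem_size` (default 1 mm, the protocol maximum; a cube is kept when
its centre lies inside the mask), each cube is split into six tetrahedra
by the Kuhn triangulation (conforming across cubes), and midside nodes
are shared to form TET10/C3D10 elements. Midside nodes sit exactly at
edge midpoints, so the geometry map is affine, Jacobians are constant and
positive by construction, and mesh volume equals kept-cube volume
exactly. The cost of this determinism is a stair-stepped boundary: the
mesh over-covers a convex body by an O(elem_size * area/volume) margin,
which at desk-scale phantom sizes is a few percent of apparent stiffness.
This geometric quantisation is a known, documented deviation from
conforming surface meshing; convergence properties are therefore assessed
on geometry both element sizes represent exactly (see Verification).

**Alignment.** Endplate surfaces are extracted as per-column extreme-z
maps; a one-sided iteratively trimmed least-squares plane rejects
side-wall columns, and three virtual landmarks per endplate (anterior
point, posterior corners) are placed on that plane. Cranial and caudal
planes from the landmark triples give the bisector plane; the model is
rotated so the bisector normal is z and the projected anterior direction
is +y, with the origin at the superior-endplate centroid. On untilted
phantoms the recovered rotation is the identity to 1e-10; a 5 deg tilt is
recovered within 0.5 deg at 0.6 mm voxels. Endplate node sets are bands
within `band` of the extreme axial levels; the default is half a voxel,
which captures the (planar) endplate faces of an axis-aligned body without
sweeping in sub-surface node layers — prescribing those would shorten the
effective specimen by an element-size-dependent amount and bias apparent
stiffness by several percent. Strongly stair-stepped (tilted) endplates
need a wider, explicitly chosen band. `Hm` is the axial distance between
the band centroids.

**Materials.** Per element, the calibrated density is averaged over a
35-point symmetric interior barycentric lattice (all positive integer
4-compositions of 8, divided by 8) with trilinear image interpolation;
the lattice's mean is the centroid, so a linear field averages exactly
(a rectangular sampling lattice folded into the tetrahedron would have
comparable density but lose that symmetry). Density maps to material via
`rho_app = rho_QCT / 0.6`, `E = 4730 rho_app^1.56` MPa,
`sigma_y = 21.7 rho_app^1.52` MPa, `E_py = 0.05 E`. The yield-stress law
carries MPa (a stress unit) — the printed unit of the source relationship
is treated as a typo. Material is computed from the element-mean density
(the alternative, averaging E itself, is exposed by calling
`material_from_density` on voxel densities before averaging). A floor of
`rho_app = 0.01 g/cm^3` (E ≈ 3.5e-2 MPa) keeps fully lytic elements from
singularising the stiffness matrix without influencing intact bone.
Poisson's ratio is not density-dependent; default 0.3, the standard
choice for homogenised bone FE, config-exposed.

## FE solve

Small-strain, geometrically linear quasi-statics — appropriate at the
1.9% apparent-strain target. J2 (von Mises) plasticity with linear
isotropic hardening integrated by radial return; the hardening modulus
`H = E E_py / (E - E_py)` makes the uniaxial post-yield tangent exactly
`E_py = 0.05 E` (a 95% post-yield modulus reduction). The consistent
algorithmic tangent matches a finite-difference derivative of the stress
update to better than 1e-6 relative.

Displacement control: the cranial endplate is driven to
`0.019 * Hm` in equal increments (default 10; automatic bisection on
non-convergence), caudal endplate fixed in all directions by default.
"Uniaxial compression" is read as axial-only prescription — cranial
transverse DOFs are free by default; `cranial='tied'` reproduces a bonded
platen, and `caudal='slide'` (axial-only with two anti-rigid-body pins)
gives the frictionless configuration used for closed-form verification.
Newton-Raphson with the consistent tangent and a backtracking line search;
the line search matters because at ~1% apparent strain most of the
trabecular continuum is at or past yield and the active plastic set
otherwise chatters between iterations. Convergence at
`||R_free|| <= 1e-6 ||F_int||`; TET10 with the 4-point Gauss rule (exact
for the affine elements' quadratic integrands); direct sparse LU with the
factorisation reused while the plastic state is unchanged (so elastic
phases factor once). Reaction = sum of axial internal forces on the
prescribed set, reported positive in compression; global equilibrium
(cranial vs caudal reaction) holds to the solver tolerance.

Nodal principal strains: the strain tensor is evaluated at each element's
ten node positions from shape-function gradients, volume-weight-averaged
over adjacent elements, and eigen-decomposed; `eps_p1 >= eps_p3`
everywhere by construction.

## Mechanical metrics

`F_U` is the axial reaction at the final 1.9% apparent strain (the
protocol's definition — not a curve maximum; under monotonic hardening
the two coincide anyway). `sigma_U = F_U / CSA`. `K` is the
least-squares slope of force vs displacement over the origin plus all
increments with zero plastic activity — the operationalisation of "the
linear range", which the protocol does not define; if yielding starts in
the first increment the first-increment secant is used (with a warning),
and a fixed-force-fraction alternative is exposed. Under pure elasticity
the regression equals the secant `F_U / delta_l` exactly.
`E_APP = K Hm / CSA`. Strain frequency tables use the nodes in the
central 50% of the endplate-to-endplate span, binned on signed strain
with fixed edges cut at |0.04|, normalised over in-range nodes. The 27
probes (2 mm radius) form a 3x3x3 lattice in the anatomical frame,
symmetric about the body centre with offsets of 25% of the body
half-extent per axis (relative, consistent placement; the protocol states
no coordinates); probe means are volume-weighted nodal averages, probes
protruding from the body are flagged rather than dropped, and a probe is
lesion-flagged when any element centroid inside its sphere lies in a
ground-truth lesion.

## Precision statistics

Per vertebra and metric: mean, sample SD (n-1 throughout; the
small-sample convention of the precision literature) and CV = SD/mean.
Across vertebrae: PE = RMS of the per-vertebra CVs. Per pair:
ARD = |A - B| / mean * 100%; for n = 2 the identity
CV = ARD / (100 sqrt(2)) holds and is tested. Intra vs inter means are
compared with a paired t-test at 0.05 with Shapiro (differences) and
Levene checks reported as flags — never silently gating the test — and
0.05/0.01/0.001 significance stars. Zero-variance differences are flagged
degenerate. SD(geometric) vs CV(mechanical) relationships use OLS with
slope-t p-values, labelled exploratory. No multiple-testing correction by
default (per-metric 0.05), Holm available.

## Verification strategy and problem sizes

Every operation is tested against an independent oracle: analytic solids
for the phantom; the affine HU law and exact OLS for calibration;
O(n^2) brute force for the mask metrics (masks <= 20^3); counting
arguments for the mesher; closed-form bars (`K = EA/L`,
`F = EA epsilon`), the patch test (affine fields reproduced to 1e-10),
the 1D bilinear elasto-plastic response (to 1e-6), finite-difference
tangents, and equilibrium for the solver; textbook formulas for the
statistics.

Mesh-size sensitivity of apparent stiffness (1.2 vs 0.8 mm elements on the
elastic phantom, < 2%) is assessed under frictionless endplates and with
the body height a common multiple of both element sizes: the clamped-end
Poisson boundary layer and the quantisation of the axial span are
properties of the boundary conditions and of the stair-step geometry
representation, not of the element formulation, and would otherwise
dominate the comparison at desk-scale phantom sizes. The half-voxel
endplate-band default matters here for the same reason: prescribing
displacement on sub-surface node layers shortens the effective specimen by
an element-size-dependent amount.

The statistical recovery suites run at deliberately scaled-down problem
sizes chosen once: bodies of ~7.5 x 6 x 15 mm (6 x 5 x 12 mm for the
planted-gradient study, which needs the finer 2 mm mesh to couple mask
volume to force without quantisation), 0.8 mm voxels, 9 mm rods, 2-3 mm
elements, two displacement increments, and 2-5 vertebrae per study over
10 master seeds. At these sizes a full
vertebra-with-five-masks cycle (render, calibrate, compare, mesh, solve
five models) takes a few seconds, and the planted effects being tested —
zero perturbation gives identically zero variability; inter-preset noise
gives larger precision error than intra in expectation; a planted
volume-noise gradient across vertebrae induces a positive
SD(RVD)-to-CV(F_U) regression slope — are scale-free by design. With two
increments the first increment is already past yield, so `K` falls back
to the secant; this affects only the stiffness statistic's label, not
`F_U`, which the recovery suites use.

## Known limitations

- Stair-stepped surfaces: no conforming surface mesh, hence a small
  systematic stiffness overestimate on curved bodies that decays with
  element size and body size.
- Uniform trabecular density with ellipsoidal lesions; no cortex,
  microarchitecture, anisotropy, beam hardening or scatter.
- The operator model is boundary-additive; it cannot produce topological
  errors (holes, split components) that real manual segmentation
  occasionally does — the largest-component step would mask them.
- Small-strain theory and monotonic hardening: no softening, damage or
  contact, so force-displacement curves are monotone.
- Precision statistics at n <= 6 vertebrae have the same low power as any
  small reproducibility study; the t-test and regression outputs are
  reported with that caveat attached (exploratory label).
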