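# Methods

This note documents the models, conventions and numerical choices behind
`coroplaque`, and what the synthetic phantoms do and do not establish about
behaviour on real images.

## Vessel phantoms

A phantom is a tube of circular cross section around a centerline
(straight, or a helix parameterized by radius and number of turns; helices
are kept gentle so tube coordinates are well defined). Two smooth radius
profiles define the geometry as functions of arclength `s`:

- lumen radius `r(s)` = baseline minus Gaussian stenoses, each given by a
  center (mm), a full width at half maximum (mm) and a fractional narrowing
  in [0, 1);
- outer-wall radius `R(s)` = baseline plus Gaussian thickenings.

Validation rejects any spec with `R(s) < r(s)`, naming the offending
arclength. The wall (`r ≤ ρ < R`) is diffuse non-calcified tissue; plaque
deposits are angular sectors of the wall over half-open axial intervals,
typed CP (calcified), NCP or LAP (low-attenuation). Deposits may not
overlap both axially and angularly, which keeps ground-truth component
areas additive: at every station
`cp + ncp + lap = vessel − lumen` exactly, with component area
`(sector/360)·wall area`. Bifurcations are landmark arclengths only — no
branch lumen is rendered; they exist to serve as co-registration anchors.

Ground truth is analytic: areas are closed-form in `s`, and true volumes
integrate the area profiles by fixed-step (0.02 mm) trapezoid quadrature.
Nothing in the truth depends on the voxel grid.

### Rendering

The analytic geometry is sampled at 3× the voxel resolution per axis
(a fixed constant; error vs cost trade-off) and block-averaged into
per-voxel tissue fractions — the partial-volume model. Each tissue has a
per-voxel HU draw from its own normal distribution; a voxel's HU is the
fraction-weighted mix of its tissues' draws, so pure voxels follow the
tissue distribution exactly. Defaults (mean, SD in HU): lumen (450, 60),
CP (700, 100) truncated below at the expected adaptive calcium threshold,
NCP (80, 30), LAP (0, 15), background (−50, 20) — chosen so default
phantoms exercise all three HU windows and both branches of the
max(350, μ+σ) threshold; all overridable. The image is then blurred with a
Gaussian PSF (default σ 0.3 mm) and given additive Gaussian noise (default
20 HU). Label volumes (background/lumen/wall) are majority-fraction
assignments of the noise-free geometry. All randomness flows from the
spec's single seed through one named generator; identical spec + seed gives
bit-identical volumes.

Not modelled: cardiac motion, beam hardening, scanner reconstruction
kernels, ultrasound speckle.

### Emulated IVUS pullback

Stations sit at 1 mm increments of pullback distance. Pullback distance is
related to arclength by a monotone PCHIP warp whose segment slopes model
pullback-speed variation: normal with mean 1 and SD 0.08, clamped to
[0.8, 1.25], with knots every ~8 mm. A mean-one slope distribution reflects
a motorized pullback whose speed fluctuates about nominal; a distribution
biased away from 1 would systematically stretch every measured volume.
Measured areas are true areas at the warp-inverse positions times mean-one
lognormal factors (coefficient of variation 0.05 by default; multiplicative
noise keeps areas positive). The measured vessel area is clamped to at
least the measured lumen area, as planimetry would enforce. Calcified and
attenuated arcs copy the deposit sectors; anchors mark pullback start, end
and each bifurcation.

### Cohorts

`sample_cohort` draws lesions with length 25–40 mm, lumen radius
1.5–1.9 mm, base wall 0.18–0.30 mm (background plaque burden ~25–35%), one
focal lesion (wall thickening 0.9–1.6 mm with a 10–45% stenosis) plus minor
lumen undulations that give the profile alignment texture, CP deposits with
probability 0.6 and LAP deposits with probability 0.5 (CP sectors in
[0°, 180°), LAP in [180°, 360°), so they never collide), 0–2 bifurcations,
25% helical centerlines, voxel 0.4 mm. These defaults are the package's
study conditions: they produce zero-CP, zero-LAP and mixed lesions whose
attenuated-plaque volumes straddle the 2/4/8 mm³ presence thresholds.

## CT quantification

Cross sections are sampled every 0.5 mm (configurable; the IVUS side is
fixed at 1 mm) on planes orthogonal to the centerline tangent, on a square
grid of pitch 0.1 mm. Membership is by label at the sample center — no
anti-aliasing; accuracy is controlled by the in-plane pitch and voxel size.
Per-sample HU is trilinear. Arclength runs proximal→distal with zero at the
ostium; intervals are closed-open in mm.

The adaptive calcium threshold uses lumen voxels after one-voxel erosion
(suppressing partial-volume contamination at the border; the uneroded mask
is the fallback for tiny lumens), computed per vessel. Classification
windows are half-open — LAP [−30, 30), NCP [30, T_CP), CP [T_CP, ∞) — so
CP + NCP + LAP + excluded areas partition plaque area exactly; wall below
−30 HU is tallied separately and excluded from TPV.

Composite Simpson integration requires uniform nodes, so non-uniform
profiles are linearly resampled first; centerline resampling chooses the
station count as round(length/step), giving exactly uniform spacing while
preserving both endpoints. When the interval count is odd the final three
intervals use the 3/8 rule. Volume additivity across an arbitrary split
point holds only to quadrature accuracy (panel regrouping); it is exact at
whole-panel boundaries.

### Resolution limits of component volumes

Component areas are the intersection of the label-based wall with an HU
window. The label boundary (voxel-majority staircase) and the HU
isocontour (trilinear) discretize each interface differently; requiring
both erodes each component by roughly a 0.05 mm shell per interface at
0.25 mm voxels. For a compact sector deposit this costs 5–10% of its
volume; with realistic contrasts the bright lumen additionally steals the
innermost LAP shell and the fat-like background donates a spurious LAP
ring at the adventitia. These are properties of HU-window characterization
at clinical resolution, not implementation defects — TPV is unaffected
(misassigned samples stay inside the wall partition), which is why total
plaque agrees with truth to ~1–2% while per-component recovery is
resolution-limited. The recovery test therefore uses a thick-walled
phantom with midpoint-matched contrasts to verify the measurement chain at
the few-percent level, and the realistic-contrast biases are left visible
in the end-to-end study (poor LAP agreement with a positive CT bias).

## Lesion detection

A lesion is a maximal run of consecutive stations with plaque burden ≥ 40%.
Stations are point measurements, so a run of k stations at 1 mm spans
(k − 1) mm and ≥ 2 mm requires ≥ 3 consecutive stations; boundaries are the
first/last qualifying stations, with no gap bridging and no half-spacing
extension. This convention changes lesion counts relative to slab-based
readings and is stated prominently for that reason.

## Co-registration

The base warp is piecewise-linear through the anchor pairs (start,
bifurcations in order, end) and is the specified contract: anchor-exact,
strictly increasing, invertible. Refinement (off by default in
`build_warp`; on by default in `run_study`, standing in for the expert
operator) aligns the z-scored lumen-area profiles, resampled at 0.25 mm,
by dynamic programming over a band of ±20% of each inter-anchor segment:
states are (position, offset) with one-pitch elastic transitions, a small
elasticity cost, and a quadratic pull toward the base map so featureless
stretches stay anchored-linear; interior knots are sampled from the optimal
path every 5 mm. A windowed cross-correlation refiner was evaluated first
and localized poorly on wide, smooth stenosis features; the dynamic
alignment roughly halves the base map's boundary error on the default warp
family (≈0.25–0.30 mm vs ≈0.43 mm mean absolute lesion-boundary error).

## Agreement statistics

Differences are CCTA − IVUS throughout. Bland–Altman limits are mean ±
1.96 × sample SD (n − 1). ICC is the two-way random, absolute-agreement,
single-measure form computed from the mean-squares decomposition of the
n×2 table (pingouin's ICC(A,1) is the cross-check in the tests).
Regression is CCTA on IVUS (IVUS on the abscissa). LAP presence uses the
IVUS attenuated-plaque volume thresholded at 2, 4 and 8 mm³ as the
reference label and sweeps the CCTA LAP volume as the score; ties are
grouped into single ROC steps and AUC is the trapezoid. Because no single
published operating point exists for the CCTA cutoff, the reported row is
the Youden-optimal cutoff (stated explicitly for audit) with a secondary
row at CCTA LAP > 0. No multiple-testing correction is applied; α = 0.05
two-sided.

## What the synthetic studies do and do not show

Passing tests establish that the measurement chain is internally
consistent: analytic volumes are recovered within discretization error,
detection and integration match independent oracles, co-registration
recovers known warps, and the agreement statistics match hand/brute-force
computations. They do not establish clinical accuracy: phantoms have
circular cross sections, clean segmentations (the labels are truth),
simplified HU statistics and no motion or reconstruction artefacts, and
the emulated IVUS inherits its areas from the same geometry rather than
from ultrasound physics. Agreement numbers from `run_study` therefore
characterize the pipeline under its stated noise model, not any scanner.

## Problem sizes

Default study sizes were chosen for desk-scale verification: 50-lesion
cohorts at 0.4 mm voxels for the end-to-end study, 100 non-voxelized cases
for warp-recovery statistics, 1,000 random profiles for the lesion-search
equivalence check, and a 0.2 mm-voxel tube for the analytic recovery check.
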