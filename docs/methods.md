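# Methods

## Problem and pipeline

Thin-cap fibroatheromas rupture when the fibrous cap between the lumen and
the lipid core fails mechanically.  `capmech` implements a slice-based
workflow for assessing and predicting plaque vulnerability from segmented
intravascular (IVUS+OCT-style) cross-section contours:

1. **Morphology** — lumen area (LA), plaque area (PA), plaque burden
   PB = PA/(PA+LA), and minimum/mean fibrous-cap thickness measured on 100
   evenly spaced lumen points grouped into four 25-point quarters.
2. **Zero-load recovery** — imaged contours are pressurized and axially
   stretched; the unloaded geometry is recovered by circumferential
   pre-shrink (fitted per slice) plus a fixed 5% axial pre-shrink.
3. **Cap mechanics** — a generalized plane-strain hyperelastic finite
   element solve at systolic pressure yields cap stress and strain
   predictors (MaxCapS, MeanCapS, MaxCapSn, MeanCapSn).
4. **Vulnerability indices** — five ordinal 1–4 indices (cap thickness,
   max/mean stress, max/mean strain) with fixed, literature-derived cuts or
   cuts calibrated against the cap index.
5. **Prediction** — a 50-tree random forest under five-fold
   cross-validation with repeated random partitions predicts the binary
   baseline→follow-up change of each index from the nine baseline factors;
   all 511 predictor subsets are swept and ranked by accuracy.

Because no patient contour set is distributed, a seeded synthetic cohort
generator stands in for the data and defines the study conditions.

## Constitutive model

All tissues are modified Mooney–Rivlin solids,

    W_iso   = c1 (Ī1 − 3) + c2 (Ī2 − 3) + D1 [exp(D2 (Ī1 − 3)) − 1]
    W_aniso = W_iso + K1/K2 {exp[K2 (Ī4 − 1)²] − 1}

on isochoric invariants Ī1 = J^(−2/3) I1, Ī2 = J^(−4/3) I2,
Ī4 = J^(−2/3) I4 with I4 = C : (n_c ⊗ n_c) for the circumferential unit
direction n_c.  Constants (kPa): vessel/fibrous tissue c1 = −262.6,
c2 = 22.9, D1 = 125.9, D2 = 2.0, K1 = 7.19, K2 = 23.5; lipid c1 = 0.5,
c2 = 0, D1 = 0.5, D2 = 1.5; calcification c1 = 92, c2 = 0, D1 = 36,
D2 = 2.0.  Lipid and calcification are isotropic (no fiber term).

The vessel c1 is negative; the model is nevertheless stable in the working
range because the exponential I1 term dominates (initial shear modulus
2(c1+c2+D1·D2) = 24.2 kPa > 0).  `materials.check_stability` scans the
incompressible equibiaxial response up to stretch 1.5 and warns on any
softening.

Near-incompressibility is enforced with a volumetric penalty κ/2 (J−1)²,
κ = 1000 × the tissue's initial shear-modulus scale (configurable through
`materials.PENALTY_FACTOR`).  At coronary pressures this keeps |J−1| below
~0.5%; the comparison against the exactly incompressible tube oracle stays
within the validation tolerances below.

## Finite element scheme

The 0.5 mm slab is modelled as generalized plane strain: in-plane nodal
displacements with a prescribed uniform out-of-plane stretch
λ_z = 1/(1 − 0.05) matching the assumed 5% axial shrinkage.  Elements are
linear triangles in a total-Lagrangian setting; the second Piola–Kirchhoff
stress is the analytic derivative 2∂W/∂C of the penalized split form
(verified against finite differences of the energy to <1e−5).  Lumen
pressure is a follower load on the deformed boundary, scaled by λ_z for the
deformed slab thickness.  Loading ramps in increments (default 10; 3–4 in
cohort mode) with full Newton iteration per increment, residual tolerance
1e−8 relative to the applied load, and adaptive step halving (≤5) on
divergence.  The annulus floats freely, so zero-mean translation and
rotation are imposed through three Lagrange multipliers; their reactions
vanish at equilibrium (<1e−8 of the load) because pressure on a closed
lumen is self-equilibrated — this doubles as a global equilibrium check.
The element tangent is assembled by central differencing of the vectorized
element residual (step 1e−7); the follower-pressure load stiffness is
exact.

### Meshing

The wall is meshed transfinitely: the lumen resampled at equal arc length
(even vertex count so alternating quad diagonals wrap cleanly), matched
outer points found by centroid rays, and radial layers interpolating
between the rings; each quad splits into two triangles.  This suits the
annular topology of vessel cross-sections, yields the circumferential
fiber direction directly from the layer tangent, and avoids an external
mesh-generator dependency.  Tissue labels are assigned per element by a
point-in-polygon test at the centroid, so material interfaces are resolved
to one element and sharpen under refinement; this is the main deviation
from boundary-conforming meshing and is invisible to the cap predictors
once the convergence loop terminates.

The loaded vessel develops a steep stress boundary layer at the lumen (the
exponential stiffening concentrates stress over ~0.05 mm).  For stress
extraction the radial layers are graded geometrically (first layer
element_size/12, growth 1.3); for the zero-load area matching a uniform
coarse mesh suffices.

### Stress recovery and predictors

Per-element fields of linear triangles are piecewise constant and carry a
volumetric-penalty checkerboard.  Scalar predictors are therefore
recovered at the 100 lumen sample points by a distance-weighted quadratic
moving-least-squares fit of the rotation-invariant maximum-principal
Cauchy stress and maximum-principal Green–Lagrange strain over the ~24
nearest element centroids in deformed coordinates.  Fitting invariants
rather than tensor components avoids averaging rotated components around
the curved boundary.  Cap aggregates (MaxCapS, MeanCapS, MaxCapSn,
MeanCapSn) are max/mean over the in-cap sample points.

Mesh convergence follows a +10% density loop (element size divided by
√1.1) until the peak cap stress changes by less than 2% between passes.

### Validation

On the annulus fixture (Ri = 1.5 mm, Ro = 3 mm, vessel constants, 13.3 kPa,
λ_z = 1/0.95) against the semi-analytic incompressible tube solution
(quadrature of the pressure–radius relation plus root finding): deformed
inner radius agrees to ~0.1%, recovered lumen-wall hoop stress to within
3% at element size 0.15 mm.

## Zero-load recovery

`apply_shrink` scales the lumen about its centroid by (1 − s) and rescales
the outer contour so the unloaded wall area equals the imaged wall area
divided by (1 − 0.05): wall volume is conserved when the vessel shortens
axially by 5%.  Internal pools follow a radial blend of the two scalings.
The per-slice circumferential shrink s is found by bisection on [0, 0.3]:
each candidate is meshed coarsely, pressurized to the imaging (systolic)
pressure with λ_z, and its lumen area compared with the imaged lumen area
(default tolerance 1%; 2% in cohort mode).  Matching on lumen area rather
than pointwise shape is robust to contour discretization; the coarse ring's
polygonization deficit is corrected multiplicatively so the criterion is
unbiased.  A warm start from the area-equivalent incompressible tube
(inverting the semi-analytic inflation relation) cuts the FE evaluations
per slice roughly in half.

## Vulnerability indices

Categories 1 (least) to 4 (most vulnerable), intervals right-closed as
printed in the reference threshold table:

| index | measurement | cuts | orientation |
|---|---|---|---|
| C | MinCapT (mm) | 0.20, 0.26, 0.36 | thinner = worse |
| MaxS | MaxCapS (kPa) | 80, 101, 110 | higher = worse |
| MeanS | MeanCapS (kPa) | 70, 88, 93 | higher = worse |
| MaxSn | MaxCapSn | 0.17, 0.18, 0.20 | higher = worse |
| MeanSn | MeanCapSn | 0.18, 0.20, 0.21 | higher = worse |

Cap thicknesses at or above a 2 mm sanity bound score 1 with a warning.
Slices without a lipid core have no fibrous cap and are excluded from all
index analyses.  The 0.20 mm thinnest-cap cut (rather than the 65 µm
histology convention) reflects in-vivo imaging: thinner categories would
be empty.

Stress/strain cuts can be recalibrated: an exhaustive search over ordered
triples of midpoints between consecutive sorted unique values maximizes
the exact-agreement rate with the cap-index labels; ties prefer higher
minimum category occupancy, then the lexicographically smallest cut
vector.  The search is exact (verified against a dense brute-force scan)
and O(m³) in the number of distinct values via prefix counts.

Outcome per matched pair: Δ = followup − baseline category, binarized to
+1 when Δ > 0 (progression toward vulnerability) else −1.

## Prediction

`RandomForestClassifier` with 50 trees (√p features per split, leaf size 1
— only the tree count is pinned by the protocol), five-fold
cross-validation with fresh unstratified random partitions per repeat
(stratified fallback only if 20 attempts leave a fold single-class),
out-of-fold positive-class probabilities averaged over repeats.  The ROC
is swept over all distinct averaged probabilities; the operating cutoff
maximizes the Youden index (ties toward higher sensitivity);
Acc/Sen/Spe follow from the confusion counts and satisfy
Acc = (Sen·n₊ + Spe·n₋)/n to machine precision.  The subset sweep
evaluates all 2⁹−1 = 511 non-empty predictor subsets with a
deterministic per-subset seed stream and ranks by accuracy (AUC ranking
available).  The reference protocol repeats the partition 100 times;
cohort-level sweeps here default to fewer repeats (5 in the analysis
scripts, noted there) to keep a full 511-subset sweep tractable on one
CPU; single-subset evaluations use more.

## Synthetic cohort

The generator emulates the study conditions the analysis assumes: 114
matched baseline/follow-up pairs across 10 patients; per-patient
dia/systolic pressures ~N(72,10)/N(140,14) mmHg; perturbed-ellipse lumens
(radius ~N(1.5, 0.22) mm), walls ~N(1.0, 0.15) mm thickened over the
plaque arc; one lipid pool per slice subtending a U(60°, 150°) arc; cap
thickness log-normal (median 0.48 mm, σ_log = 0.564) — chosen analytically
so ~69% of baseline slices fall in the thickest-cap category and ~6% in
the thinnest, matching the observed right-skew.  Follow-up geometry
applies a morphology-linked multiplicative drift to cap thickness
(log-change = −0.04 − 1.2·(PB − 0.62) − 0.15·log(capT/0.45) + N(0, 0.18))
and a small lumen-area drift; with these defaults roughly 15 of 114 pairs
cross a cap category upward (class imbalance of order 16 vs 98) while the
drift's dependence on baseline burden and cap thickness keeps the outcome
learnable.  A `strong()` variant (larger coefficients, less noise) is used
for signal-recovery checks, a `null()` variant for chance-level checks.
Imbalance is produced by the small mean drift, never by label
subsampling.

What the generator does *not* emulate: multi-pool lipid geometries (single
pool by default), calcification mechanics, segmentation noise and
inter-observer variability, patient-level clustering of progression, and
any direct stress/strain signal — mechanical predictors arise only through
the FE stage.  Passing tests therefore demonstrate internal consistency
and parameter recovery under the stated conditions, not clinical
performance on real images.

## Numerical choices and degenerate inputs

* Polylines are stored counter-clockwise without the duplicate closing
  vertex; areas by the shoelace formula, no smoothing.
* The 100-point sampling starts at the vertex farthest in +x from the
  contour centroid (ties toward smaller y) and proceeds counter-clockwise,
  fixing quarter labels reproducibly.
* Cap membership: a lumen point is "in the cap" when the outward centroid
  ray through it crosses a lipid pool; cap thickness is the minimum
  distance to the nearest lipid border; multiple pools share one pooled
  cap statistic; calcification does not interrupt membership.
* Slices whose lipid subtends no sample ray warn and report absent cap
  statistics.
* Zero-pressure solves use an absolute residual floor (1e−10) since the
  relative criterion degenerates.
* Shrink bisection with an infeasible tolerance raises an iteration-limit
  error; FE non-convergence at a candidate shrink is skipped with a
  warning and the bracket adjusted inward.
* Degenerate CV folds (single-class training sets) trigger repartitioning,
  then a stratified fallback with a warning.

## Known limitations

* Linear triangles with a volumetric penalty lock mildly; the MLS recovery
  and graded boundary layers compensate, but very coarse meshes
  (element size ≳0.5 mm) carry a few percent stress bias.
* The transfinite mesh requires the outer contour to be star-shaped about
  the lumen centroid — true for the synthetic cohort and typical coronary
  cross-sections, not for extreme crescent geometries.
* Residual stress (opening angle) and patient-specific material constants
  are out of scope; stress/strain magnitudes inherit the literature
  constants' uncertainty.
* Prediction metrics on the synthetic cohort characterize the pipeline,
  not any patient population.
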