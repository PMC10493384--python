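# Methods

This note records the models, parameter choices and numerical conventions
behind `phantomforge`, and what the synthetic-data tests do and do not
establish.

## Conventions

Voxel indexing is 0-based; world coordinates are millimetres in one fixed
LPS-style frame; `voxels[i,j,k]` maps to world space through
`origin + direction @ (spacing * (i,j,k))`. HU are floats in memory and
int16 on disk. The nominal CT range [−1024, 4000] HU is a *soft* invariant:
`CTVolume.validate()` reports excursions but nothing clips. This is
deliberate — the phantom lungs noise model (mean −932.64, SD 63.12 HU)
places ~7 % of its mass below −1024, and clipping there would bias the
recovered mean by ≈ +3 HU, defeating parameter-recovery checks whose
tolerance is 3·SD/√n ≈ 0.6 HU.

## Compartment segmentation

HU ranges are closed integer intervals, kept exactly as published. Two
consequences are surfaced rather than silently repaired:

- the patient air-lung and interstitium ranges overlap on [−750, −749];
  resolution is by priority (air lungs > interstitium) and the overlap is
  listed in the coverage report;
- two phantom-scheme bounds are printed self-contradictorily (hi < lo);
  the built-in scheme reads bone as −236…domain-max and V-lesion as
  −586…−432, both overridable.

Priorities are: lesion V > lesion NV > vascular > bone > lungs >
interstitium > fat = muscle, mirroring the Boolean subtractions of the
source workflow (lesion carved out of vascular/muscle, interstitium out of
fat). Region growing uses 26-connectivity; the auto-seed is the voxel of
the largest in-range connected component nearest its centroid —
deterministic, and correct whenever the target is the dominant in-range
structure. Tests that emulate an operator pass explicit lesion seeds
(mask centroids); `segment_compartments` drops out-of-range explicit seeds
with a note and falls back to auto-seeding, so a noisy seed voxel cannot
abort a whole acquisition.

Segmentation is restricted by default to an automatic body mask (largest
connected component of HU > −900, cavities filled). Without it the scan
field's air would be labelled "air lungs" and every comparison against
anatomy-only ground truth would be meaningless; excluded exterior voxels
are counted in the coverage report. Voxels above the domain maximum join
the highest compartment (the "no HU gap" rule); skin, which has no HU
range of its own, is available as a morphological shell of the body mask
(default 2 voxels) and is excluded from DSC/HU tables by default.

## Infill calibration and planning

The calibration curve is piecewise-linear through the cube-sample means,
monotonized by isotonic regression (weights = ROI voxel counts) and
anchored at (0 %, air HU) and (100 %, densest-target HU). Nothing in the
physical workflow suggests a parametric form, so the interpolant is
assumption-free and exactly invertible; the inverse returns the lowest
infill attaining a given HU (flat segments resolve downward). Planning
clamps out-of-span targets (with a warning), quantizes to a 2.5 % step
(the finest value in the published plan) and floors load-bearing
compartments — by default only the air lungs — at 10 %, the published
scaffold minimum.

The published per-compartment infills {10, 35, 40, 50, 55, 62.5, 70}
happen to be monotone in the published patient mean HU, so a single
monotone curve consistent with both exists; `reference_calibration_curve()`
is exactly that curve and serves as the synthetic "true" printer response.
The cube phantom's HU values are not published numerically, so the package
ships a cube-scan generator rather than hard-coded read-off values.

## Meshing and STL

Surfaces are the 0.5-level marching-cubes isosurface of the binary mask,
zero-padded (so border-touching masks still close) and replicated 2× per
axis first: on the raw binary grid marching cubes chamfers every voxel
toward an octahedron and a single voxel would enclose only 1/6 of its
volume; at 2× the bias is ~3 % for 10-voxel structures and vanishes with
size. Meshes are exported unsimplified; zero-area triangles are dropped at
write time with a warning. Binary STL is the default dialect.

## Rigid registration

The transform is `y = R(x−c) + c + t` with `R = Rz·Ry·Rx` (Euler angles,
radians) and `c` fixed at the fixed-image centre — the source never states
a rotation centre, and the volume centre is the standard, well-conditioned
choice. The metric is mutual information from a 32-bin joint histogram
(intensities clamped to [−1024, 2400]; per-evaluation bin edges spanning
the sampled range) over 3000 points drawn uniformly in one random 40-mm
cube of the fixed domain per iteration. The gradient is estimated by
central finite differences (0.5 mm step) on parameters scaled so a unit is
≈1 mm of boundary motion, using common random numbers and frozen histogram
edges across the stencil — without those two the stochastic metric's noise
would swamp the differences. Updates follow the normalized gradient with a
decaying step `a_k = a0/(k+10)^0.602`, `a0` halving across the four pyramid
levels (Gaussian smoothing σ = 8, 4, 2, 0 mm, no downsampling). Iteration
counts, sample counts and the subregion edge are not reported for the
original study; the defaults here (100 iterations/level) were chosen for
robust recovery of ≤10 mm / ≤5° misalignments on the synthetic chest
(20/20 within 1 mm/1° at the fixed master seed) in a few seconds per
registration. `converged` compares head-vs-tail moving averages of the
final level's metric, with tolerance scaled to the spread of the local
metric across subregions (different cubes have genuinely different MI).

Mask propagation uses nearest-neighbour interpolation (values stay exactly
binary); images use trilinear with −1024 fill. Comparisons always run in
the reference (source-CT) geometry.

## Synthetic data: the stated world

The digital chest is parametric-analytic — elliptical body cylinder with
fat (and optional skin) shells, two lung ellipsoids with an interstitial
shell, spine/sternum columns and rib arcs, a small mediastinal vascular
tree, and a 62-mm spherical lesion at the inferior-medial border of the
left lung, split into a vascularized cap (fraction 0.4, toward the
inferior-medial border) and a non-vascularized remainder. Analytic
geometry gives exact, pairwise-disjoint ground-truth masks with no asset
files. The vascular tree is deliberately smaller than the V-lesion and
disconnected from it through lung air, so that both region-growing
auto-seeding and the V/vascular priority subtraction behave as in the
source anatomy.

Compartment HU are i.i.d. Gaussian per voxel with means/SDs from the
published per-compartment statistics (patient column and six phantom
scanner/kVp columns ship as presets). Scan-field air is N(−1000, 10) HU
and optional skin N(−5, 20) HU — neither is tabulated in the source;
values are CT-typical and fixed once. The virtual phantom scan draws each
compartment at its transfer HU with a default noise SD of **20 HU**: a
typical quantum-noise magnitude for chest CT at these techniques. The
published per-ROI SDs (45–100 HU) are *not* used as scan noise because
they fold in tissue texture and partial volume, not just noise.

What a green synthetic test does not establish: real CT noise is spatially
correlated by the reconstruction kernel (i.i.d. voxel noise is harsher on
threshold segmentation); partial-volume effects, beam hardening and
kVp-dependent HU shifts are not physically modelled (per-scanner presets
differ only in their tabulated means/SDs); and printed-PLA texture is not
emulated. The full-loop DSC bands are therefore regression bands fixed a
priori from the published ranges (lungs ≥ 0.85 against printed 0.89–0.9;
each lesion sub-compartment ≥ 0.60 against printed minima 0.66/0.69), not
claims of numeric reproduction.

Two published-number inconsistencies propagate, by design, into synthetic
results: the patient NV-lesion mean (−36.27 HU) lies outside the published
NV range (−425…−375), so a noiseless chest segments every compartment
exactly except NV (DSC 0, its voxels falling in fat's range); and the
phantom V/NV means likewise sit outside the printed phantom lesion ranges.
The full synthetic loop avoids the dead end the way the original
semi-automatic workflow did: the design stage can plan from curated masks
(`run_design(..., masks=...)`), and the phantom re-segmentation uses a
scheme adapted to the known transfer values (Voronoi cells of the transfer
HU on the CT axis) with operator-style lesion seeds.

## Degenerate inputs and tie-breaks

Both-empty masks give DSC 1.0 with a flag (vacuous agreement); one empty
gives 0.0. Empty compartments yield NaN statistics with a warning, never
an exception. Priority ties in segmentation break by scheme order (earlier
wins). Infill quantization rounds to the nearest step, ties upward. A
metric subregion with effectively constant fixed intensity contributes a
zero metric and no update. SD is the sample SD (ddof = 1) by default with
a population-SD flag.

## Known limitations

No slicing/G-code, no printer drivers, no physical scanner model, no
deformable registration, no statistical test between scanners (the source
names none). DICOM support is read-only and restricted to uncompressed
explicit-VR little-endian series. The registration reference path is pure
Python/scipy; it is fast at the shipped volume sizes but not optimized for
clinical-resolution volumes.
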