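# Methods

This note documents the models, numerical choices and limitations of the
package; it is the place to look before changing a default.

## Cortical geometry and equivolume layering

Surfaces are handled implicitly as signed distance functions (SDFs) sampled
on the functional voxel grid, negative toward white matter and positive
toward CSF; a boundary is the zero level set. `compute_sdf` evaluates the
exact Euclidean distance from voxel centres to a triangle mesh (KD-tree
prefilter on triangle centroids, exact point–triangle distance on the
candidate set, sign from the nearest face normal; mesh normals must point
toward CSF).

The two intermediate laminar surfaces are placed by the equivolume
principle: cortical layers keep their volume fraction through folds, so a
target volume fraction must be converted into a distance fraction using
local curvature. Along a cortical column, with `t` the distance from the WM
surface and `k1, k2` the WM surface's principal curvatures at the column's
foot, the cross-sectional area grows as `A(t) = (1 + k1 t)(1 + k2 t)`, so
the cumulative volume is `V(t) = t + H t² + K t³/3` with `H = (k1+k2)/2`,
`K = k1 k2`, and the boundary at grey-matter volume fraction `f` solves
`V(t_f) = f·V(h)` for local thickness `h = sdf_wm − sdf_pial`.

*Curvature estimation.* Principal curvatures are taken from the WM SDF's
Hessian (the second fundamental form of its level sets, via the
tangent-projected Hessian's trace and second invariant) and transported to
the zero level set along the normal with `k(0) = k(t)/(1 − t·k(t))`. This
choice — rather than a mesh-based cotangent scheme — keeps the whole
layering stage on the voxel grid and reproduces the cylinder and sphere
closed forms (`r_f = sqrt((1−f) r_wm² + f r_pial²)`,
`r_f = ((1−f) r_wm³ + f r_pial³)^{1/3}`) to well under 1 % on phantoms.
Denominators are clipped (`1 − t·k ≥ 0.1`, `1 + k·h ≥ 0.05`) to stay finite
near the medial axis and in strongly concave folds; `V(t_f) = f·V(h)` is
solved by 48 bisection steps (monotone integrand, ~1e-14 relative
tolerance). A ribbon thinner than one voxel raises an error naming the
offending location.

The intermediate boundary SDF is the thickness-fraction interpolation
`(1−g)·sdf_wm + g·sdf_pial` with `g = t_f/h`; it is exact for parallel
boundaries and keeps the four boundaries depth-ordered by construction.

*Voxel volume distribution.* Each voxel is sampled on a regular
`subdivision³` lattice (default 4, i.e. 64 points — a balance between the
0.8-mm grid and phantom accuracy; Monte-Carlo cross-checks agree within
0.02 per entry); each sample is classified by the sign pattern of the four
boundary SDFs (trilinear interpolation between voxel centres), giving rows
that sum to 1 exactly. Voxels with zero GM fraction stay in the matrix —
their WM/CSF weights absorb non-laminar signal in the spatial GLM — but are
excluded from ROI eligibility.

## Boundary-based registration

The BBR objective is `1 − mean(tanh(0.5 · Q))` over mesh vertices, where
`Q` is the percent intensity contrast between samples taken 1 mm outside
and inside the surface along the vertex normal (`Q > 0` when the
GM side is brighter, as in T2*-weighted EPI); the cost is invariant to
global intensity scaling by construction. Seven parameters (three Euler
angles, three translations, log phase-axis scale) are fitted with
three Nelder-Mead passes of shrinking initial simplex (0.03 rad / 1 mm /
0.02 log-scale down to 6 %), `xatol = 3e-4`. Non-convergence is flagged on
the result, never silent. An error is raised when more than half the
boundary samples fall outside the volume.

The recursive variant bisects the registered mesh into equal-vertex halves
along cardinal axes (cut axis cycling through one of the six x/y/z
permutations, repeating after three levels; default six iterations),
re-fitting each partition started from its parent's solution. Partitions
below 50 vertices are left as-is. The final per-vertex displacement is the
component-wise median over the six permutation runs, which suppresses an
ordering whose partitions latched onto the wrong edge. Partition refits are
*bounded* — translations within ±2 mm of the parent solution, rotations
±0.2 rad, log-scale ±0.1 — because an unbounded derivative-free search on a
small patch occasionally jumps to an aliased intensity edge several mm
away; EPI distortion corrections are physically bounded, so the cap costs
nothing in scope. Whether the 7th degree of freedom is re-estimated per
partition is a flag (`refit_scale`, default on).

*Precision.* On clean phantoms the discretised cost's minimum sits
~0.05–0.15 mm from the true pose (trilinear-interpolation ripple at 0.8-mm
resolution); this is the intrinsic per-fit precision, and recursion
compounds it for a minority of vertices. Region-level displacement recovery
(median over a partition-sized region) is accurate to ~0.03 mm, i.e. well
within a tenth of a voxel, and recursive registration never decreased the
absolute GM–WM boundary contrast relative to the global fit on any phantom
tested.

## ROI selection and weighting

The localizer GLM fits two HRF-convolved block regressors plus intercept
per voxel, with T maps for (45+135) vs baseline and 45 vs 135.
Zero-variance voxels are excluded and logged. Selection restricts to an
anatomical mask ∧ activation `t > 2.3`, requires a strictly positive
(negative) orientation T for the 45°- (135°-) preferring ROI, and takes the
top 500 per orientation with ties broken by voxel index, so selection is
deterministic. Weighting z-scores each voxel's course per run (robust to
inter-run offsets; the choice of per-run rather than concatenated scoring
is ours) and multiplies by |T|; `raw` mode bypasses both steps for the
control analysis.

Layer balancing removes, from the currently dominant layer, the member
voxel with the largest fraction in that layer until a one-way ANOVA over
per-voxel GM-layer fractions gives p > 0.1 (observations are the three
per-voxel layer fractions; the loop stops at 3 voxels per layer and warns
if balance was not reached).

## Laminar extraction and response estimation

The spatial GLM solves `Y = X·B` per volume by QR (columns of X are
correlated between adjacent layers; QR avoids squaring the condition
number, and a warning fires at cond > 1e3). All-zero compartment columns
are dropped and flagged; their rows return NaN. The interpolation
estimator `B = XᵀY/N` is tagged separately and never feeds inference by
default.

Temporal design: one GLM per task over that task's runs. Events — both
presentations and omissions — are unit sticks at the *expected* first
grating onset (cue onset + 750 ms SOA; for an omission the expectation
pertains to the moment the grating would have appeared), convolved with the
canonical double-gamma HRF (peak delay 6 s, undershoot delay 16 s, unit
dispersions, peak:undershoot 6, 32-s kernel, peak normalised to 1 so betas
are per-event amplitudes), built at 16× oversampling and sampled at volume
times. Nuisance: per-run motion parameters, backward-difference derivatives
(first volume zero) and squared derivatives; all-zero columns dropped with
a log entry; per-run intercepts. The discrete-cosine high-pass
(cutoff 128 s, constant excluded) is applied identically to data and
design. R² is computed on filtered data around run means. Betas can be
rescaled to percent signal change via the fitted run intercepts
(`scale="percent"`), which is exact on noiseless data.

The orientation-specific reduction subtracts the non-preferred from the
preferred orientation's beta per layer and condition within each ROI and
then averages the two ROIs; it is exactly antisymmetric under swapping the
orientation labels.

## Inference

`rm_anova` (statsmodels `AnovaRM` underneath) handles the fully
within-subject 3-way and 2-way designs with uncorrected degrees of freedom
(no sphericity correction by default, matching how such designs are
conventionally reported; a constant table returns F = 0, p = 1 with the
proper dfs). An independently written brute-force sums-of-squares partition
serves as the oracle in the test suite. Paired t tests are two-sided with
df = n−1; zero-variance differences flag an infinite t. Within-subject SEM
removes subject means, restores the grand mean, and applies the Morey
factor `sqrt(C/(C−1))` (toggleable). tSNR is mean/SD over time (SD with
ddof = 1).

## The synthetic data model

*Phantoms.* Flat slab, cylinder annulus, sphere shell (closed-form depth
and equivolume boundaries) and a sinusoidally folded sheet (numeric SDF;
for Monte-Carlo and qualitative tests). Orientation preference is laid out
in alternating 2-voxel columns so both ROIs sample every depth; an optional
fraction of unselective voxels supports the ROI-size dilution analysis.
The pipeline's default phantom is the cylinder annulus: on a perfectly
grid-aligned slab all ROI voxels share a handful of depth profiles and the
5-column spatial design matrix degenerates, an artefact real cortex does
not have.

*Session design.* 4 runs × 2 blocks × 64 trials (512 trials, 256 per task,
tasks alternating by run), exact 25 % omissions and exact orientation
counterbalance per block, cue-colour contingency flipped after half the
runs, ITI jittered as a truncated exponential on [2.15, 5.15] s with the
mean one-third into the range, 750-ms cue→grating SOA. Grating difference
columns carry the published mean deltas (3.3°, 6.9 % contrast) rather than
live staircase output, since the deltas do not enter the BOLD model.

*Staircase.* Weighted up-down: one step down after a correct response,
three steps up after an error, floored at zero, which equilibrates at 75 %
correct by construction. The observer is a cumulative Gaussian
(`p = Φ(Δ/σ)`, chance 0.5). The running threshold is the mean of the last
reversals. Simulated asymptotic accuracy sits ~1–2 points above 75 % (the
usual finite-step-size bias of up-down rules).

*BOLD forward model.* Voxel baseline = compartment mix × per-compartment
EPI intensity (WM 427, GM layers 455/456/461, CSF 430); response =
Σ_layers (voxel layer fraction × bias gain × condition amplitude in %),
convolved HRF sticks at expected-grating onsets; linear + slow-cosine drift
(default 0.5 %); i.i.d. Gaussian noise (default SD 36.6, putting GM tSNR
near 12.5); optional bounded rigid translations recorded in the motion
table and, by default, *not* applied (volume realignment is an upstream
step). The mixing weights come from the phantom's analytic equivolume
boundaries, not from the layering module, so forward model and analysis are
independent — with one deliberate exception: the HRF/event-regressor code
is shared between simulator and temporal GLM, which is precisely the
assumption a GLM makes about its data. Passing round-trip tests therefore
validates the partial-volume and laminar logic, not HRF misspecification,
vascular nonlinearity, draining-vein spatial correlation or physiological
noise, none of which the generator models.

*Default truth.* Presented gratings: orientation-specific response in all
layers (preferred 1.2 %, non-preferred 1.0 %). Omissions: −0.2 % baseline
dip in all conditions (omission trials in a stimulus-rich run sit below the
session mean), plus a +0.12 % deep-layer preferred-orientation component in
the orientation task only. Superficial bias gains (0.9, 1.0, 1.2) emulate
the gradient-echo draining-vein bias.

## Problem sizes

The test suite and acceptance checks run on deliberately small instances
chosen as the smallest sizes that still discriminate: phantoms of 18–32
voxels per side (0.35–0.8 mm), sessions of 2–4 runs × 16–32 trials for
voxel-level checks, the full 512-trial session for design-structure checks,
registration meshes of ~700–1700 vertices, 100 × 18-subject datasets for
power checks and 2000 replicates for type-I calibration. Group-level power
and calibration operate on per-subject effect tables generated directly at
a calibrated signal-to-noise level (deep-layer omission t ≈ 3) rather than
on thousands of full voxel-level simulations; the voxel-level path is
validated separately by the exact noiseless round trip.

## Known limitations

- Equivolume curvature comes from finite differences of the SDF; on
  geometry curved at the scale of one or two voxels the boundary placement
  degrades before the error is flagged.
- Registration precision is bounded by the discretised cost (~0.1 voxel
  per fit); displacement fields are piecewise-rigid with median blending,
  not smooth, and purely translational/rotational symmetries of a phantom
  (e.g. along a cylinder axis) are cost-degenerate directions in which the
  optimiser may drift harmlessly.
- No draining-vein deconvolution or depth-dependent HRF; no slice-timing
  model (3D acquisition); no prewhitening (plain OLS throughout).
- The folded-sheet phantom's intermediate "truth" layers are equidistant,
  not equivolume, so it is not used for exact-recovery tests.
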