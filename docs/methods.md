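# Methods

This note records the models the package implements, the defaults it ships
with and why, the numerical choices that were genuinely open, and what the
synthetic phantoms do and do not establish about real data.

## Relaxometry model and fitter

Each voxel's magnitude signal across the series is modelled as a
monoexponential in the varied timing parameter:

* T1 series (varying repetition time): `S(TR) = M0 (1 − exp(−TR/T1))`
* T2 series (varying echo time): `S(TE) = M0 exp(−TE/T2)`

Both exponents are negative — saturation recovery grows toward M0 and
spin-echo decay falls from M0; positive exponents would be unbounded and
non-physical.

The fitter is deliberately plain steepest descent on the
**sum** of squared residuals (not the mean), with analytic gradients
∂S/∂M0 and ∂S/∂T and a single shared learning rate for both parameters.
Defaults: `m0_init = 8000`, `t1_init = 150 ms`, `t2_init = 75 ms`,
`loop_limit = 75000`, `learning_rate = 1e-6`. A step that makes T non-finite
or ≤ 0 is clamped to `positivity_floor` (10⁻³ ms). An optional early stop
(relative parameter change < `early_stop_tol`, default 10⁻¹⁰) makes clean
voxels finish in a few thousand iterations; setting it to 0 restores the
fixed-loop behaviour exactly, and the loop limit is always a hard cap.

**Conditioning caveat.** At these signal scales the loss curvature along M0
is ~10³–10⁴ times smaller than along T, so raw descent with a shared 10⁻⁶
step traverses the T direction quickly but the M0 direction extremely
slowly: starts whose true M0 is far from `m0_init` do not converge within
the loop budget. This is a property of the algorithm, not a bug, and is why
every default phantom compartment puts M0 at the fitter's native scale
(8000). For wide parameter ranges a diagonally preconditioned variant
(`step_mode="scaled"`: each step divided by the Gauss–Newton diagonal, with
a ±50% per-step trust region so overshoots cannot land in the flat T→0
region where gradients vanish) is available behind a flag and off by
default; it recovers (M0, T) across M0 ∈ [2000, 16000], T1 ∈ [50, 600] ms,
T2 ∈ [20, 200] ms to < 0.5%.

`fit_map` vectorizes the identical per-voxel update (a numba kernel);
because the fit depends only on the signal vector, voxels with bit-identical
curves are optionally deduplicated and fitted once — a large win on
piecewise-constant noiseless phantoms, a no-op on noisy data. The
background mask defaults to voxels whose maximum signal exceeds 5% of the
volume maximum. Repetitions are arithmetically averaged per time point
(after any registration) before fitting. All-zero voxels are reported as
degenerate and dropped from the fitted mask rather than raising.

`nls_oracle_fit` is an independent check: log-linear regression for clean
T2 decays (exact for a true monoexponential, including the two-point closed
form `T2 = (TE₂−TE₁)/ln(S₁/S₂)`), bounded nonlinear least squares
otherwise. It is used only in tests and QC, never in the pipeline path.

## Motion correction

Inter-acquisition motion is modelled as a 2D rigid transform (rotation +
translation, no scaling) per volume, estimated from ≥ 2 named landmarks on
one representative slice by closed-form orthogonal Procrustes (centroid
alignment + SVD of the 2×2 cross-covariance, reflections excluded) and
applied identically to every slice with bilinear interpolation,
zero-filled at the borders to match magnitude-image background. Coincident
source landmarks make the rotation ill-posed; the estimator then returns a
flagged translation-only transform. All volumes are mapped into the frame
of a chosen reference volume; whether the original analysis chained
transforms between consecutive acquisitions or used a common reference is
ambiguous, and the common-reference formulation was adopted and recorded in
outputs. Per-slice estimation is intentionally out of scope: one transform
per volume, as stated for the source analysis.

## Morphometry and statistics

Brain size is summarized by landmark-pair Euclidean distances in mm (brain
length: olfactory-bulb tip → tectum end; maximum tectum width; maximum
brain height), each normalized to the same specimen's skull width so groups
are compared on proportion rather than size; skull width is treated as the
fourth representative measurement. Landmark placement is manual in the
source workflow, so automated detection is out of scope — landmarks arrive
in tables. Group comparisons use the two-sample two-tailed t-test with
pooled variance by default (Welch by flag, since group variances can differ
visibly); no multiple-testing correction is applied by default, matching
per-measure reporting, with Holm available behind a flag of the caller's
choosing. The t p-value is validated in tests against numerically
integrated t tails and an exhaustive permutation oracle; on tiny discrete
samples (n = 4 binary data) the t approximation deviates from the exact
permutation tail by ~0.28, which the test documents.

## ROI intensity

White-matter signal is the mean of a `roi_size × roi_size` (default 2×2)
pixel block in the periventricular grey zone divided by an equal block in
the optic tectum on the same slice — white over grey, flippable and recorded
in outputs. Footprint anchoring is bit-exact: upper-left corner =
`round(center − (size−1)/2)` per axis (numpy round-half-even). Slices are
the reference slice at the caudal end of the rhombencephalic ventricle plus
`n_extra_slices` (default 2) moving rostrally. The per-specimen summary is
the arithmetic mean of the per-slice ratios (aggregation was not specified
in the source workflow); per-slice values are always emitted so alternates
can be computed. The ROI reads the T2-weighted intensity volume at a chosen
TE by default; operating on fitted maps is supported.

## G-ratio

Per fiber, g = axon-boundary perimeter / myelin outer-boundary perimeter,
from simple closed polygons with implicit closure; 0 < g < 1 is enforced
(axon strictly inside myelin, checked with exact geometry predicates).
Axon diameter (P/π) and myelin thickness (ΔP/2π) use
perimeter-equivalent-circle conventions for consistency with the
perimeter-based g; area-equivalent variants are provided by flag because
field usage varies, and whether a Feret or perimeter diameter was used in
the source analysis is not stated. An optional report bins g by
axon-diameter quantile, guarding against diameter shifts confounding group
comparisons.

## Synthetic phantoms: what they emulate and what they do not

The phantom is an ellipsoidal brain (grey matter with an embedded
periventricular white-matter band) inside an ellipsoidal skull shell on a
desk-scale 48×24×28 grid at 0.22 mm voxels — proportions, not the native
305×140×165 @ 0.036 mm acquisition matrix, which remains constructible by
config for profiling. Compartment parameters are configuration values, not
claims about zebrafish tissue, placed so the TR/TE sets straddle the
relaxation times: grey (M0 8000, T1 150 ms, T2 75 ms), white (8000, 110,
45), skull (1500, 300, 20). Default geometry (skull width 4.30 mm, brain
4.55 × 3.09 × 2.65 mm) keeps every cohort specimen inside the grid and the
skull at ±3σ of the 5% biological CV (size draws are clipped at ±3σ for
that reason); the resulting normalized length/height sit near reported
wild-type values while the normalized width is smaller than reported, a
concession to the fixed-width skull shell.

Imaging follows the acquisition design: per time point the signal model is
applied voxelwise, per-acquisition rigid motion (default sub-pixel: 0.5 px
translation SD, 0.3° rotation SD) is injected, and Rician magnitude noise
`√((S+n₁)² + n₂²)` is drawn per repetition — 4 repetitions for T1 series, 9
for T2, as acquired in practice. Default σ = 170 corresponds to SNR ≈ 40
against the peak T2-weighted signal. Cohort deltas default to the reported
effect directions and magnitudes: mutant brain scaled by
0.841/0.873/0.876 along length/width/height and white-matter T2 × 1.25
(which moves the expected white/grey T2w ratio from ≈ 0.72 to ≈ 0.85 at
TE = 36.6 ms). Fiber sets realize each drawn g exactly (the axon polygon is
the myelin polygon scaled by g about the shared center), with optional
radial tracing jitter; defaults take the published group statistics
(0.593/0.085 and 0.690/0.076).

Passing tests on these phantoms demonstrates that the algorithms recover
known ground truth under the stated acquisition timing, noise model and
effect sizes. They do not establish performance on real data: the phantoms
have no partial-volume effects, no B1/flip-angle or sequence (RARE)
artifacts, no spatially varying noise, perfectly known landmarks, and
piecewise-constant tissue. The printed group values from real specimens are
used only as simulation settings, never as quantities the pipeline is
claimed to reproduce.

## Determinism and orchestration

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; cohort specimens and pipeline stages spawn
child seeds deterministically, so identical config + master seed reproduces
every numeric output bit-identically (checked by hashing run directories).
The pipeline config is YAML with a versioned schema in which unknown keys
are errors; each stage directory carries a provenance record (config
snapshot, seeds, package version, wall time). Stage outputs are
append-only: no stage mutates another stage's directory.

Problem sizes used by the test suite and the acceptance script — the
default 48×24×28 phantom, 500 replicates for the morphometry power study,
200 for the image-level ROI power study, 200 fibers per G-ratio group —
were chosen once as desk-scale study conditions that keep the full suite in
the minutes range while leaving comfortable statistical margins.

## Known limitations

* Raw gradient descent with the shipped learning rate must start near the
  true M0 scale (see the conditioning caveat); signal scales far from
  M0 ≈ 8000 should use the scaled mode or rescale their data.
* Registration is strictly in-plane rigid; through-plane or deformable
  motion is out of scope, as is intensity-based registration.
* The length measurement quantizes its rostro-caudal endpoints to slice
  indices (≤ 1 voxel per endpoint), a faithful model of manual annotation
  but a visible error floor on coarse grids.
* Multi-exponential relaxation, B1 correction and k-space/RARE simulation
  are out of scope.
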