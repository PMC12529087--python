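# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `myotract`. It is the package's own account of what it
computes; every number quoted here is produced by the test suite or the
acceptance script.

## The simulated muscle

The phantom is an approximately bipennate muscle: a stack of elliptical
cross-sections with a flat, one-voxel-thick central aponeurosis sheet into
which the fibers insert. On a 50 × 50 × 40 grid at 1 × 1 mm in-plane
resolution and 6-mm slice thickness, 37 slices carry tissue, with one
proximal and two distal zero-padded slices. The ellipse semi-axes grow
linearly from (8, 14) voxels at the proximal tissue slice to (12, 20) at
the distal slice, so cross-sectional area — and with it fiber length —
varies along the muscle. The aponeurosis spans 75% of each slice's ellipse
row extent; keeping the sheet shorter than the ellipse is what lets fibers
fan radially around its ends, so the azimuth φ covers all four quadrants
(a full-width sheet would make every muscle voxel's nearest aponeurosis
voxel lie in its own row and collapse φ to {0°, 180°}).

Fiber orientation per muscle voxel:

- φ (azimuth) is the in-plane direction of the displacement from the
  voxel's nearest aponeurosis voxel in the same slice, i.e. fibers point
  radially away from the sheet.
- θ (elevation) ramps linearly from 66.4° to 82.0° with the weighted sum
  (weights 0.5/0.5) of the normalized tissue-slice index and the min–max
  normalized in-plane distance from the aponeurosis. The min–max
  normalization guarantees the stated range is attained exactly at the
  extreme slice/distance corners.
- ε₁ = (cos θ cos φ, cos θ sin φ, sin θ) in (x, y, z) = (+column, +row,
  +slice) axes. Aponeurosis voxels get ε₁ = ẑ (collagen perpendicular to
  the slice plane).

Each tissue voxel carries the tensor D = E L Eᵀ with eigenvalues
(2.1, 1.6, 1.4) × 10⁻³ mm²/s (FA 0.209, inside every tracking window used
here), ε₃ = normalize(ε₁ × ẑ) and ε₂ = ε₁ × ε₃. For aponeurosis voxels,
where ε₁ ∥ ẑ makes that cross product degenerate, the frame falls back to
the coordinate axes; these tensors are never tracked because tracts
terminate at the muscle-mask boundary.

Units: diffusion weighting b = 475 s/mm², eigenvalues in mm²/s, so
b·λ₁ ≈ 1 — a physically sensible attenuation. All internal lengths are mm.

## Signal synthesis and noise

Signals follow the single-tensor model S = S₀·exp(−b rᵀ D r) with S₀ = 1,
one b = 0 image and 12 directions from an antipodally symmetric
electrostatic-repulsion arrangement (projected gradient descent on the
sphere, best of three seeded restarts; the 12-direction scheme reaches a
minimum antipodally folded pairwise angle of ≈ 39°). Noise is additive
zero-mean Gaussian on the real channel with σ = S₀/SNR, applied to every
voxel of every image; each Monte-Carlo trial draws from an independent,
reproducible substream keyed by (root seed, trial index). SNR levels 39
and 54 are the realistic in vivo conditions studied.

## Tensor estimation

Per-voxel weighted linear least squares on ln S: an ordinary
least-squares pass followed by a weighted pass with weights equal to the
squared predicted signals — the standard two-pass log-linear scheme.
Non-positive signals are clamped to a small floor and the voxel flagged.
Eigenvalues are sorted descending and not clipped; ε₁ is sign-normalized
to a non-negative slice component (tracking re-aligns locally anyway).
Noise-free, the fit recovers the ground-truth tensor to < 10⁻⁹ relative
error at every muscle voxel.

## Seeding schemes

**APO.** The muscle–aponeurosis boundary of each slice is extracted by
marching squares at the half-voxel level, resampled arc-length-uniformly
to `mesh_cols` points (closed curve, deterministic start and orientation),
then resampled across slices to `mesh_rows` rows; the default simulation
mesh is 40 × 40 (≈ 1 seed per boundary voxel). Mesh normals are the raw
cross products of the local row- and column-direction tangents in mm
space, unsmoothed. Each vertex is a seed. Because rounding a boundary
point can land it in the aponeurosis (mask value zero — the tract would
fail to initiate), the updated lookup rounds the slice coordinate, takes
floor and ceiling of the row and column coordinates, tests the four
candidates against the muscle mask, and uses the in-muscle candidate
nearest the seed in mm (ties broken in the fixed candidate order) to
supply the initial direction; the tract still starts at the seed point
itself. On the default phantom the skip rate is zero. Skipped seeds are
reported, never silently dropped.

**VXL.** Integer-voxel seeds at every second row and column (every third
in vivo is the published practice) inside a once-eroded muscle mask,
every slice. **EDGE.** The boundary layer of the once-eroded mask
(eroded minus twice-eroded) plus the once-dilated aponeurosis mask
intersected with muscle. Morphology is 2-D per slice with a 3 × 3
(8-connected) element — at a 6:1 slice anisotropy, 3-D erosion would
hollow out entire slices.

## Tracking

Euler integration of ε₁ with nearest-voxel direction lookup (a
sign-coherent trilinear lookup exists behind `TrackOptions(interp=
"trilinear")` but is off by default) at a physical step of one in-plane
voxel width (1 mm); the step is converted to voxel
coordinates by dividing each component by the voxel dimension, so 6-mm
slices advance 1/6 voxel per step. APO tracts propagate in +Z only; VXL
and EDGE tracts propagate bidirectionally and the reverse branch is
reversed and concatenated, dropping the duplicated seed once. Direction
sign is aligned to the previous step (first step to ±Z).

Termination: leaving the muscle mask (reason `boundary`); FA outside
[0.1, 0.4] (simulation; 0.05–0.40 is the in vivo preset) (`fa_window`);
or the angle between the propagated segment and the second segment
preceding it exceeding 30° on two consecutive points (`angle`) — the two
offending points are removed, which keeps noise spikes out of the
quantification. A 1000-step cap flags pathological loops. On the
noise-free phantom no `fa_window` or `angle` termination occurs, for any
scheme.

For VXL/EDGE, up to four innermost points are removed if they lie in
aponeurosis voxels. With muscle-only termination this rarely triggers on
the phantom (see the limitations below), but the rule is implemented and
tested. Tracts shorter than 5 mm are excluded (10 mm / α > 25° /
κ > 20 m⁻¹ is the in vivo tibialis-anterior preset). Smoothing fits the
row, column, and slice coordinates to 2nd-, 2nd-, and 3rd-order
polynomials in point number; tracts too short to fit pass through with a
warning flag.

## Quantification

- **L_FT**: summed Euclidean inter-point distance (mm) of the smoothed
  tract.
- **α (pennation)**: per point, the angle between the chord from the seed
  point (innermost point for bidirectional tracts) and the central-axis
  tangent at the seed's slice, folded to [0°, 90°]; the tract value is the
  point mean, and the whole-muscle value the mean of tract means.
- **Central axis**: 3rd-order polynomial fits of the slice-wise mask
  centroids; tangents from slice-wise forward differences of the fitted
  positions, in mm.
- **κ (curvature)**: Frenet–Serret κ = |r′ × r″| / |r′|³ with analytic
  derivatives of the fitted polynomials (coordinates in mm), reported in
  m⁻¹; parameterization-invariant by construction.
- **γ, β (APO only)**: γ is the elevation of the first smoothed segment
  out of the aponeurosis tangent plane (90° minus its angle to the mesh
  normal at the seed vertex); β = α − γ. γ uses the smoothed tract,
  consistent with all quantification happening after smoothing.
- **FSS**: greedy farthest-streamline subsampling under the symmetric
  mean-closest-point distance, computed on tracts resampled to 15
  arc-length-uniform points (keeps selection tractable at several
  thousand tracts); seeded from the longest tract, ties to the lowest
  tract id. Sample sizes 1000 and 500 mirror the published conditions.

## Evaluation

Agreement is assessed segment-wise: each smoothed-tract segment's angle to
the central-axis tangent at its midpoint slice is paired with the
ground-truth angle (ε₁ vs the same tangent) at the segment's voxel.
Bland–Altman mean difference and 1.96-SD limits of agreement, and the
two-way mixed consistency single-measure ICC(3,1) from the standard
ANOVA decomposition, summarize the pairs. On the default noise-free
phantom the APO pipeline yields ICC ≈ 0.997 and a mean difference of
≈ 0.003°; at SNR 54 and 39 the ICC drops (≈ 0.7 and ≈ 0.6) and the limits
widen but remain centered on zero, and mean curvature inflates
SNR-dependently — the expected noise behavior.

Sampling uniformity bins smoothed tract points by nearest voxel. The
headline points/voxel mean, SD, and CV aggregate the slice-wise means
across slices — across-slice uniformity is what farthest streamline
sampling targets, and it is the quantity whose published values are
internally consistent; voxel-level statistics over all mask voxels
(zeros included) are also reported, as is % filled with the full mask as
denominator (which therefore cannot exceed 100%).

The Monte-Carlo experiment repeats noise → fit → track → filter → smooth
→ FSS → quantify per trial and reports the population mean and the percentile
(2.5/97.5) 95% CI of the trial means; `ci_method="normal"` switches to a
mean ± 1.96 SD interval. Trials with zero surviving tracts are counted
and excluded. The published design uses 1000
trials; the test suite runs a handful of trials per SNR, which is enough
for every monotonicity check it asserts, and the full-size experiment is
available through `myotract run --trials 1000`.

## Reproducibility

One root seed drives everything: the encoding optimization, and per-trial
noise substreams derived by trial index, so the Monte-Carlo experiment is
reproducible and parallelizable. Seed sets are deterministically ordered;
FSS and tracking are deterministic given their inputs. Re-running a
pipeline configuration reproduces numerically identical CSV outputs.

## Limitations

- The phantom's geometric constants (ellipse schedule, aponeurosis
  extent, θ ramp weights) are module defaults chosen to satisfy the
  qualitative design (slice-varying radii, radial φ, stated θ range), not
  measured values; whole-muscle architecture numbers are therefore
  geometry-dependent and are not comparison targets.
- Single-tensor Gaussian diffusion only: no multi-compartment models, no
  k-space/EPI artifacts, no gradient nonlinearity. Noise is additive
  real-channel Gaussian by default; `add_noise(..., rician=True)`
  switches to magnitude (Rician) noise but is off everywhere in the
  shipped pipelines.
- Tracts terminate at the muscle-mask boundary, so they stop at the
  aponeurosis rather than crossing it; the trim rule exists for
  conventions in which tracts can enter the sheet.
- On this phantom, APO all-tract sampling is already slice-uniform, so
  FSS500 does not reduce the across-slice CV for APO (it does for VXL and
  EDGE); passing FSS tests here says nothing about voxel-level speckle in
  sparser real data.
- No statistical comparisons between schemes are produced, and figures
  are limited to raw plot data (CSV).
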