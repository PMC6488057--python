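# Methods

## Conventions and units

Arrays are indexed `(x, y, z)`, 0-based, x the fast in-plane axis and z the
slice axis; a voxel's world position is `origin + index * spacing` (mm).
Activity volumes are converted to Bq/mL once on load (DICOM rescale
slope/intercept applied per slice) and every later quantity is unit-tagged:
concentration Bq/mL, SUV g/mL, volume mL, AUV g, SI/ASI percent. A voxel
belongs to a muscle ROI iff its mask label equals that muscle's id — masks
are assumed voxelized upstream, and no partial-volume weighting is applied.

## SUV, AUV and decay correction

The SUV denominator uses the injected activity decayed from injection time to
scan start, `A(t) = A₀ · 2^(−t/T½)` with T½ = 109.77 min for F-18. The
direction of the correction (decaying the dose forward vs decay-correcting
the image back) is algebraically symmetric; decaying the dose was fixed as the
convention. Within-scan (per-bed-position) decay is not modelled: a single
global correction is applied to the whole volume. "Total activity in muscle"
is computed as mean ROI concentration × ROI volume, which makes the muscle
SUV exactly the mean of the voxelwise SUV map over the ROI, and AUV = SUV ×
volume equals the sum of voxelwise SUV × voxel volume (both identities are
asserted to 1e-9 relative in tests).

## Symmetry analysis

SI is antisymmetric under limb swap, scale-invariant, and bounded in
[−200, 200]%; ASI = |SI|. Group summaries report median (range) and the
number of subjects strictly above a 25% ASI threshold (a subject exactly at
the threshold does not count). Paired comparisons use the Wilcoxon
matched-pair signed-rank test: zero differences are dropped (the common
convention; the alternative of keeping them half-weighted changes nothing at
the sample sizes involved), |differences| are midranked, and for n ≤ 20 the
two-sided p is exact — the null distribution of W⁺ is built by convolution
over doubled midranks, equivalent to enumerating all 2ⁿ sign patterns; p =
min(1, 2·min(P(W ≤ w), P(W ≥ w))). Above n = 20 a tie-corrected normal
approximation with continuity correction is used. No multiple-testing
correction is applied across muscles by default (a Holm adjustment is
available but off), mirroring an uncorrected per-muscle α = 0.05 analysis.
The normality screen is the classical one-sample Kolmogorov–Smirnov test
against a normal with the sample mean/SD; with estimated parameters this is
anticonservative (the Lilliefors situation), which is documented rather than
corrected because the screen only motivates the switch to the non-parametric
test.

## Heterogeneity

Skewness is the population-style g₁ = m₃/m₂^{3/2}. No small-sample bias
correction: muscle ROIs contain thousands of voxels, where g₁ and the
adjusted G₁ differ negligibly, and g₁ has the simpler invariance contract
(exact location/scale invariance, sign flip under negation). Histograms use
equal-width bins over [min, max] with a right-closed last bin (default 50
bins, configurable); constant input makes skewness undefined and raises.

## Cluster index

Hot count m = max(1, round(0.05·N)) with half-up rounding keeps the realized
hot fraction as close to 5% as the ROI size allows and guarantees a nonempty
hot set; ties at the cutoff are broken by lexicographic voxel index
(deterministic) and flagged in the output. NHN uses 6-connectivity with all
face-neighbours weighted equally despite the anisotropic (1.6, 1.6, 2.0) mm
voxels — the index is a topological statistic, not a metric one. Neighbours
outside the muscle ROI are excluded entirely: they are neither hot nor cold.
The correction factor is generalized to (1−f)/f for a configurable hot
fraction f, equal to 19 at the default f = 0.05. Under uniformly random hot
placement the expected index is ≈ (m−1)/(19m) ≈ 0.053, *not* 1 — the ×19
normalization equalizes counts, not adjacency odds — so the index is
interpreted against the provided permutation null (uniform reshuffles of the
hot flags over ROI voxels, seeded; empirical p = (1 + #{null ≥ observed}) /
(n_perm + 1)). Compact hot blobs yield indices above 1 in practice, the
regime read as clustered. Degenerate cases: a single hot voxel forces index
0; zero cold-mean NHN with positive hot-mean reports +inf with a flag; both
zero reports NaN with a flag.

## Synthetic phantoms

The generator reproduces the statistical structure the analysis assumes and
nothing more. Muscle ROIs are ellipsoids (voxel centre inside the surface) on
a 44 × 44 × 60 grid of 1.6 × 1.6 × 2.0 mm voxels — small enough that the full
suite runs in seconds. Background uptake is i.i.d. gamma(k, θ) per muscle:
one parameter (k) controls the right tail via skewness 2/√k, and mean k·θ is
set from a target SUV. Spatial clustering is injected by multiplying
spherical blobs (centres uniform over ROI voxels) by an amplitude factor; the
blob voxel sets are recorded as ground truth. The non-dominant limb is the
x-mirrored geometry (mirroring is an involution) whose ROI values are rescaled
so the realized pre-smoothing mean ratio hits the target SI exactly — scaling
to the realized rather than the analytic mean removes blob-placement jitter
from the ground truth. Finally a 3 mm FWHM Gaussian filter (σ = FWHM/2√(2 ln 2)
≈ 1.274 mm, converted to voxel units per axis) emulates scanner
post-smoothing; it is applied after blob injection and is mean-preserving in
the ROI interior, so ground-truth SUV is recovered to ≤1% on eroded
(interior-only) ROIs while full-ROI SUV is biased low by boundary spill-out —
a real partial-volume-like effect that cancels between the two mirrored limbs,
which is why SI recovery stays within ±3 points.

What the phantoms do **not** emulate: anatomy, Poisson sinogram noise,
scatter/randoms, attenuation effects, registration error, or spatially
correlated background texture. Passing recovery tests therefore validates the
estimators and their implementation, not robustness to real acquisition
physics.

Default study conditions (10 subjects): six muscle pairs, two per segment
(pelvis, thigh, lower leg), with mean SUV 0.6–2.4 g/mL, gamma shapes spanning
skewness ≈ 0.7–2.6, and per-muscle median ASI from 5% (thigh-like symmetry)
to 42% (gastrocnemius-like asymmetry). Per-subject SI is drawn from
N(0, median_asi/0.6745) so the direction of asymmetry is random across
subjects while the median |SI| matches the muscle's nominal ASI; injected
dose ~ N(53.6, 1.8) MBq and body mass uniform on 55.5–91.7 kg.

## Numerical choices

- Exact signed-rank enumeration switches to the normal approximation above
  n = 20 (2²⁰ ≈ 10⁶ sign patterns is the practical exactness limit; the DP
  convolution keeps even that cheap).
- Hot-voxel ties: stable argsort on descending value, so equal values resolve
  to the lowest lexicographic index.
- Quartiles for box-plot summaries use linear interpolation; outliers are
  points beyond q1 − 1.5·IQR or q3 + 1.5·IQR, whiskers at the most extreme
  inliers.
- Report CSVs are written at %.17g so summary statistics recompute exactly
  from the per-subject records file, and re-runs with the same seed are
  byte-identical (permutation seeds are derived via SHA-256 of
  seed/subject/side/label, independent of process state).
- Gaussian smoothing uses zero-padding boundaries ("constant" mode), which is
  what makes boundary spill-out physical rather than artificially renormalized.

## Known limitations

- DICOM support covers single-frame image series with uniform geometry;
  multi-frame and gantry-tilted series are rejected rather than resampled.
- The KS normality screen's anticonservatism is inherited by design (see
  above).
- The permutation null assumes exchangeability of hot flags across ROI
  voxels; strong within-ROI trends in uptake would violate it.
- The cluster index compares limbs and muscles only through their own ROIs;
  no cross-subject spatial normalization is attempted.
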