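# Methods

This note documents the models behind each measurement chain, the
synthetic-data generators used to validate them, the numerical choices
that required a decision, and what the tests do and do not demonstrate.

## Fiber-field simulator

Fiber networks are rendered as straight anti-aliased segments on a
non-negative raster. Straightness reflects that gel collagen fibers are
locally straight at the ~100 µm tile scale; curvature is out of scope.

* **Orientations** are axial (unoriented lines, domain [0, π)). They are
  drawn from a von Mises distribution with mean `orientation_mean_rad`
  and concentration κ, folded modulo π; κ = 0 is isotropic, κ = ∞ is a
  single orientation. Note the folding halves the effective axial order:
  the order parameter is I₂(κ)/I₀(κ), so κ = 1 (~0.11) is only barely
  anisotropic while κ = 8 (~0.78) is strongly aligned. This matters when
  interpreting score differences at small κ.
* **Geometry**: centers uniform over the image (fibers may cross and may
  extend past the border); radius and length normal-distributed with
  floors at 10% of the mean to keep them positive. Defaults — 0.3 µm
  pixels, a 200 µm (667 px) field, 200 fibers, radius 0.6 ± 0.15 µm,
  length 60 ± 15 µm — emulate a dense collagen gel imaged at multiphoton
  resolution (a 620 µm/2048 px field of view corresponds to the same
  0.3 µm pixel pitch).
* **Intensity**: overlapping fibers combine by *maximum*, not sum, since
  SHG intensity of crossing fibers is not calibrated additive; this also
  keeps Otsu binarization well-posed. Anti-aliasing ramps coverage
  linearly over half a pixel at the fiber edge.
* **Noise**: optional Poisson on (background + signal), then additive
  Gaussian (default SD 5 on a background of 10 and fiber intensity 100),
  then clipping at 0. All randomness flows through one
  `numpy.random.default_rng(seed)` per image; batches use
  `base_seed + i`.

## Alignment score

Per tile (default 100 µm, non-overlapping, row-major, partial edge tiles
discarded — a 200 µm field gives exactly 4):

1. subtract the tile mean and apply a separable Hann window (the window
   suppresses the axis-aligned cross artifact of the periodic FFT
   boundary; `window="none"` reproduces the raw-FFT variant for
   comparison with ImageJ-style analyses);
2. FFT, center the spectrum, zero the DC bin, take |·|²;
3. restrict to the central disk of half the Nyquist radius
   (`central_fraction=0.5`, configurable — the low-frequency "central
   maxima" region carries the fiber-scale anisotropy; the high-frequency
   tail is noise-dominated);
4. fit the power-weighted second-central-moment ellipse; axes are
   2·√eigenvalues, orientation is the principal eigenvector.

The score is minor/major ∈ [0, 1]: 1 ⇔ circular spectrum ⇔ no preferred
orientation; → 0 ⇔ strong alignment. It is invariant to uniform
intensity scaling (moments are power-normalized) and to quarter-turn
rotation. Constant tiles have no defined score and are excluded from
summaries. Both per-tile scores and the image mean are reported, since
either aggregation is defensible for plotting.

A moment ellipse was chosen over an explicit contour fit because it is
deterministic, parameter-light, and exact for the degenerate cases
(rank-1 spectrum → 0; circularly symmetric spectrum → 1).

With 200 fibers per 200 µm field (~50 per tile), finite-sample
anisotropy puts the isotropic-field score around 0.82–0.9 rather than
exactly 1; the aligned-field floor (~0.12) reflects the finite fiber
length and radius, which spread spectral power off the principal line.

## Local thickness

Thickness at a foreground pixel is the diameter of the largest inscribed
disk containing it. Treating pixels as unit squares, the inscribed-disk
radius at center c is r(c) = EDT(c) − ½ (floored at ½ so every
foreground pixel carries at least a 1 px disk), where EDT is the
distance to the nearest background pixel center. The map is computed by
painting disks in decreasing-radius order and keeping the running
maximum; this is exactly the brute-force definition, and the tests
assert pixel-exact equality against an independent all-pairs oracle on
random 64×64 masks. The −½ offset keeps the classic bias of
EDT-based thickness (a solid disk of radius 10 px reads ~20 px, a 1 px
line reads 1 px, a fiber of radius r px reads ~2r).

Summaries (mean/median) are reported over all foreground pixels by
default, or restricted to the skeleton (`on_skeleton=True`), which
removes the rim-weighting of wide fibers.

## Skeleton lengths

The fiber mask is skeletonized (scikit-image); branches run between
endpoints/junctions (degree ≠ 2 nodes in the 8-connected skeleton
graph), measured with 1 px axial and √2 px diagonal steps, scaled to µm.
Branches under 3 px are pruned as skeletonization spurs. Isolated cycles
are traced once. Skeleton end-erosion shortens a fiber by roughly its
half-width at each end — negligible for fibers much longer than thick,
which is the regime the generator produces. The length estimator is a
stated stand-in: the original sphere-fitting analyses never published a
length algorithm.

## Pillar-movie simulator

Pillar tops are rendered as isotropic Gaussian spots (σ default 0.4 µm)
at rest positions on a regular grid (default 5×5, pitch 4 µm — simulator
conventions; elastomer arrays commonly fall in this range), moving as

    x_i(t) = rest_i + drift · t + F_i(t) / k

with k the spring stiffness (default 20 nN/µm) and drift a rigid
per-frame translation. Ground truth therefore satisfies k·d = F exactly
at every frame. Frames default to 0.5 Hz (2 s interval), 30 frames,
0.1 µm pixels. Force events default to a linear ramp reaching a plateau
at mid-movie, emulating a cell's late spreading phase.

**Noise convention.** The simulator offers Poisson shot noise
(photon-limited: peak-SNR = √peak counts) and additive Gaussian read
noise. The validation movies use the photon-limited convention —
peak 100 counts on background 10 gives peak-SNR 10. The Fisher
information of a Gaussian spot with free amplitude/offset/width puts the
per-coordinate localization bound at ~0.05 px under these conditions,
and the tracker's fit reaches it; under a pure read-noise model with
peak/σ = 10 the corresponding bound is ~0.08 px, so quoted localization
figures always state the noise convention.

## Pillar tracking and forces

1. **Detection** (frame 0): local maxima above background median + half
   the peak excess, separated by ≥ pitch/2, refined by a 2D Gaussian
   least-squares fit in a half-pitch window with one reweighted pass
   (weights ∝ model intensity — near-efficient for shot noise); fallback
   to background-subtracted centroid, flagged. Detections are ordered by
   pitch-binned row then x so grid ids are stable against subpixel
   jitter.
2. **Tracking**: each pillar is re-localized per frame around its
   previous position; a candidate farther than pitch/2 marks the pillar
   lost for that frame (it keeps its last position, flagged). Tracks are
   then smoothed with a centered 5-frame moving average (10 s at 0.5 Hz —
   short against the force-buildup timescale). Frame 0 is left raw so
   the zero-force reference cannot absorb any early loading ramp.
3. **Drift**: drift(t) = mean over cell-free reference pillars of
   x(t) − x(0); identically zero at the reference frame. References are
   user-specified ids (preferred, mirroring manual selection of
   cell-free regions) or auto-selected as the lowest-total-motion
   quartile. Correction subtracts drift(t) from every track and refuses
   to run twice (it is not idempotent).
4. **Forces**: d(t) = x(t) − x_ref with x_ref the frame-0 position
   (default) or, with `reference_mode="extrapolate"`, the intercept of a
   linear fit over the first half of the movie — unbiased whenever early
   motion (drift + loading ramp) is near-linear, and about half the
   noise of a single-frame reference; the recovery pipeline uses this
   mode. F = k·|d|; per-pillar peak = max over frames; the movie summary
   is the mean of peaks over engaged pillars, with the time-averaged
   force also emitted (either average is a defensible per-cell
   statistic).

Validated recovery: programmed 5/10/15 nN plateaus with (0.1, 0.05)
µm/frame drift at peak-SNR 10 are recovered within 5%; drift-only null
movies yield a post-correction median force below 0.2 nN (2% of a 10 nN
reference).

## LFQ simulator and statistics

The simulator draws per-protein base abundances log-normal across
proteins (log₂ mean 23, SD 2 — the scale of MaxQuant LFQ intensities),
adds within-protein log₂ noise of SD 0.5 (~40% CV, typical LFQ
reproducibility), shifts a chosen fraction of proteins by a log₂ effect
in group 2, and applies logistic MNAR dropout in log₂ abundance
(P(missing) = σ(intercept + slope·log₂x); negative slope makes weak
signals vanish more often). Truth labels (+1/−1/0) accompany the matrix.

**Imputation**: per protein, m = minimum over observed non-zero
intensities across all samples ("for each protein" is read per-row, not
globally); missing cells are drawn from Normal(m/100, (m/100)/100).
Observed values are never touched; negative draws (rare at SD =
mean/100) are clipped to 0 and counted in the run log; proteins with no
observed value cannot be imputed and are dropped with an explicit
report. Draws are seeded.

**Testing**: equal-variance two-tailed t-tests by default (the
unqualified reading of "unpaired t-test"; Welch by flag), BH q-values,
and regulation calls of up/down for significant proteins with linear
mean ratio ≥ 1.5 or ≤ 1/1.5. Because the significance gate is ambiguous
between raw p < 0.05 and q < 0.05 in common practice, calls under both
gates are always emitted (`call`, `call_on_q`); the default gate is raw
p. Zero-variance-in-both-groups proteins get p = 1 (equal means) or the
smallest positive float (unequal), flagged, rather than NaN. Proteins
observed in only one group are still tested after imputation but the
result is imputation-driven; downstream interpretation should treat
them as presence/absence calls.

Calibration (asserted in tests): on full-null simulations the raw
p < 0.05 rate is 0.05 ± 0.015 and the BH false-discovery proportion at
q < 0.05 stays within Monte-Carlo tolerance of 0.05 over 200 replicates.

**RNA side**: RPKM = count · 10⁹/(length_bp · library_size), exactly
linear in counts and inverse-linear in depth. Housekeeping stability
uses the exact-method two-sided Mann–Whitney per gene (scipy), suited to
n = 3 vs 3 where the discrete null matters: fully separated groups give
p = 2/20 = 0.1, the enumeration minimum for a two-sided test at that
sample size.

## Problem sizes used in validation

Alignment semantics use 50 images per condition (4 tiles each);
monotonicity uses 20 seeds per κ ∈ {0, 1, 2, 4, 8}; thickness exactness
uses 50 random 64×64 masks plus radius-recovery at 2/4/6 px; force
recovery uses 5×5 arrays over 30 frames; calibration uses 200 null
matrices of 2000 proteins at 6 vs 6. These sizes give stable Monte-Carlo
estimates for every asserted tolerance while keeping the default test
run quick on a laptop.

## What the synthetic data does not capture

* Fibers are straight, non-branching, and rendered without an optical
  PSF; real SHG fields have curved, bundled, out-of-plane fibers and
  speckle. Passing recovery tests shows the estimators are correct for
  their stated geometric model, not that segmentation of real gels is
  solved.
* Pillar spots are symmetric Gaussians; bright-field pillar images are
  ring-like and defocus-sensitive. Drift is rigid translation only.
  Substrate coupling between pillars is not modeled.
* LFQ noise is log-normal and independent across proteins; real data
  have correlated batch structure, peptide-level effects and
  normalization artifacts that the procedure inherits untested.
* The κ = 1 condition is nearly isotropic under the folded-von-Mises
  convention, so score differences between κ = 0 and κ = 1 sit at the
  Monte-Carlo noise floor of the standard validation sizes; rank-based
  monotonicity checks account for this.

## Known limitations

* Skeleton lengths under-measure by the fiber half-width at open ends
  and split crossing fibers at junctions; the estimator targets branch
  statistics, not per-fiber identity.
* `local_thickness` is exact but O(foreground × disk area); for large
  rasters with thick structures prefer downsampling.
* The tracker assumes pillars never move more than pitch/2 between
  frames (true at the simulated drift and 0.5 Hz frame rates; faster
  drift requires pre-registration).
* Equal-variance t-tests on linear-scale LFQ intensities are the
  procedure being reproduced, not a recommendation; heavy-tailed data
  are better served by the Welch flag or log-scale analysis.
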