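# Methods

## Problem and model

Given a reference image *R* and a sensed image *S* of the same scene, image
registration estimates the planar projective transform *T* (3×3, acting on
row homogeneous coordinates, eight degrees of freedom) aligning the two.
Classical pipelines commit to one source of information — one keypoint
detector in the sparse (feature-based) route, or one similarity measure in
the dense (intensity-based) route — and different choices yield different,
individually plausible transforms.

This package treats that choice as an uncertainty to be reasoned about.
The candidate transforms T₁…T_Q produced by Q different generators form a
frame of discernment Θ. Three evidence sources score every candidate: the
normalized cross-correlation (NCC) between *R* and the candidate-registered
sensed image, computed on the gray intensities, on Canny edge maps, and on
phase-angle reconstructions (inverse FFT of a unit-magnitude spectrum
keeping only the phase). Per channel *c* the scores are clamped to [0, 1],
contrast-stretched with y = eˣ − 1, and normalised into a Bayesian basic
belief assignment

    m_c(T_i) = (e^{NCC_i} − 1) / Σ_j (e^{NCC_j} − 1).

The three channel BBAs are fused into a combined BBA m with Dempster's rule
(conjunctive combination renormalised by the conflict) or with n-source
PCR6, which redistributes every fully conflicting mass product back to its
contributors in proportion to the mass each committed. The combined
transform is formed in inverse space,

    T_c⁻¹ = Σ_i m(T_i) · T_i⁻¹,

an entrywise mass-weighted average of the t₃₃-normalised inverse matrices;
the sum is inverted and renormalised. The registered image is the sensed
image warped by T_c (inverse mapping, bilinear resampling, fill 0 with a
validity mask).

With a known ground truth T_true, quality is scored by AAID — the mean
absolute intensity difference between *R* and *R* warped by the composite
T_true·T_c⁻¹, which is the identity exactly when T_c = T_true — globally
and on an even 5×5 spatial partition whose pixel-count-weighted mean equals
the global value by construction.

## Candidate generators

**Sparse.** Keypoint detection and description through adapters over
scikit-image's SIFT, ORB and CENSURE+BRIEF families; Lowe ratio matching
(default ratio 0.8, one-to-one by greedy best-distance-first); MSAC (or
RANSAC) consensus over 4-point minimal samples (threshold 2 px, 2000
iterations, seeded and deterministic); least-squares re-fit on the inliers
via Hartley-normalised DLT plus Levenberg–Marquardt refinement of the
squared reprojection cost (the literal sum-of-distances cost is available
as an option). A consensus carried by fewer than 6 inliers is treated as a
stage failure: four correspondences determine any projective hypothesis
exactly, so agreement below that redundancy level is not evidence. A failed
generator is dropped from the frame with a warning; fusion requires at
least two survivors.

Adapter defaults deviate from the library's where the library's are tuned
for high-contrast photographs: ORB's FAST threshold 0.01 (library 0.08) and
up to 2000 keypoints; CENSURE's non-maximum threshold 0.02 (library 0.15).
Low-contrast synthetic textures otherwise yield too few corners to support
consensus.

**Dense.** The rigid 3-parameter model (anticlockwise rotation θ in
degrees, about the reference-image center by default, plus translations
(tv, th) in pixels) is searched directly for the maximum of MI, NCC or
PSNR. The search is a deterministic two-stage procedure: an exhaustive
coarse grid (defaults: θ ∈ [−30°, 30°] step 1°, translations ∈ [−30, 30] px
step 2 px) evaluated on a block-averaged pyramid level with minimum
dimension ≈ 64 px — per angle the sensed image is warped once and the
translation sweep runs as integer pixel shifts of the rotated image — then
Nelder–Mead refinement of the full-resolution objective from the three best
coarse nodes. The refined value never falls below the full-resolution
objective at the best coarse node (asserted in tests). The full projective
dense search is out of scope: direct search over an 8-dimensional objective
is intractable, which is precisely the regime for the sparse route.

## Numerical and design choices

* **Coordinates.** (v, w) = (column, row), 0-based, pixel centers at
  integers; row-vector convention `[g h 1] ~ [v w 1]·T` throughout, with a
  single transposition boundary for column-vector libraries.
* **Masked similarity.** Both the dense objective and the per-candidate
  channel NCCs are evaluated over the valid warp region (the mask the warp
  returns), not the full fill-0 frame. Pixels with no sensed-image source
  say nothing about alignment quality; including them as zeros biased
  NCC/PSNR optima by up to tens of pixels on textures with a bright or
  graded background, because the objective then rewards overlap size over
  alignment. At the true parameters the valid region covers exactly the
  informative content, so the masked optimum is unbiased. The literal
  full-frame objective remains available (`SearchConfig(masked=False)`).
  AAID evaluation, by contrast, stays literal over all M·N pixels (an
  optional masked variant exists but is off by default).
* **Overlap floor and coarse MI binning.** Dense hypotheses with less than
  50% valid coverage are rejected; within the default ±30 px/±30° bounds
  the true motion always retains more. The coarse stage bins MI at 32
  levels (full resolution keeps the 256-bin definition): a 256² joint
  histogram on the ~10³-pixel overlaps of the pyramid level is sample
  starved, and its positive bias grows as the overlap shrinks, which
  otherwise hijacks the coarse argmax.
* **NCC of a constant image is 0** by convention (the measure is undefined;
  edge maps of featureless regions are the common case). **Negative NCCs
  clamp to 0** before the stretch, since eˣ − 1 < 0 would produce negative
  masses. A channel whose stretched scores all vanish falls back to a
  uniform BBA with a warning, keeping the three-source structure intact.
* **MI uses base-2 logarithms** (bits) over 256 equal-width bins on [0, 1];
  only the ordering matters downstream, so the base is free but fixed.
* **PSNR** uses peak 1.0 on [0, 1] data — identical to the 8-bit 255-peak
  formula, since numerator and denominator rescale together.
* **Canny defaults**: σ = 1.4142, double thresholds at 0.1/0.2 of the peak
  gradient magnitude of the smoothed image; all exposed in configs.
* **Gauge of the inverse average.** The weighted matrix average is
  gauge-sensitive for genuinely projective candidates; this package fixes
  t₃₃ = 1 before averaging and records the choice in every result.
* **Dempster guard.** Conflict K > 1 − 10⁻¹² raises a total-conflict error
  (advice: use PCR6, which is total); mass sums are validated to 10⁻⁹ with
  no silent renormalisation.
* **BetP** (pignistic transform) is provided for probabilistic read-out but
  is not wired into the registration chain: the combined transform is a
  mass-weighted blend of all candidates, not a decision for one of them.

## Synthetic study conditions

No public dataset accompanies the method, so all experiments run on
generated pairs. Four deterministic 128×128 textures (smoothed-noise blobs;
a checkerboard under a smooth random gain, so edges exist but periodicity
is broken; blobs over a linear ramp; a two-scale blob mix resembling
stained tissue) serve as references. Sensed images are produced by warping
with a known transform and optionally adding zero-mean Gaussian noise of
variance 0.01 on the [0, 1] scale (σ ≈ 25.5 gray levels on 8-bit data),
clipped to [0, 1].

The packaged 20-scenario suite covers, per texture: the rigid design
θ = 10° anticlockwise, (tv, th) = (−10, 5) — rotation about the image
center, as simulated sensed images are conventionally produced — noise-free
and noisy; the mirrored noisy design θ = −10°; and one mild random
projective motion (rotation ≤ 5°, scale within 3%, translations ≤ 8 px,
perspective terms |t₁₃|, |t₂₃| ≤ 10⁻⁴) noise-free and noisy for the sparse
route. Scenarios serialise to JSON and replay bit-identically.

What the generator does **not** emulate: occlusion, parallax from depth,
illumination fields, sensor-specific noise (Poisson, banding), resolution
mismatch between the two views, and real tissue morphology. Passing tests
therefore demonstrate the correctness and internal consistency of the
fusion chain under controlled geometric/noise conditions, not performance
on real multi-camera or histology data.

## Problem sizes and determinism

Suite images are 128×128 and the dense coarse stage runs at 64×64; a full
three-measure dense search takes ~15 s and the whole 20-scenario fused
suite a few minutes on one core. Every stochastic component (MSAC sampling,
noise draws, texture seeds) is driven by explicit integer seeds; repeated
runs are bit-identical.

## Known limitations

* The combined transform averages inverse matrices entrywise; for large
  rotations this is not an intrinsic (e.g. geodesic) average, and for very
  discrepant candidates the blend can be worse than the best single
  candidate (it is bounded by the worst in practice on the suite, and this
  is asserted, but not guaranteed by construction).
* The two combination rules agree closely when one candidate dominates the
  evidence; on the packaged suite their AAIDs differ by at most ~17%
  relative. When one generator returns a mediocre-but-confident candidate,
  divergence can exceed 20% on other random suites — PCR6 is the more
  cautious rule and keeps more mass on the weaker candidate.
* Binary-descriptor families (ORB, BRIEF) degrade sharply at noise
  σ = 0.1 on smooth textures; the pipeline relies on candidate dropping
  and evidence down-weighting rather than making every detector robust.
* The dense route is rigid-only by design; mild projective motion must go
  through the sparse route.
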