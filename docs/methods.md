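# Methods

This note records the models behind `lfpmatch`, the parameters that matter,
what the synthetic data does and does not emulate, and the design choices
made where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Enhancement

The enhancement chain assumes an 8-bit photograph of either an inked
control (dark ridges, light card) or a powder-developed latent print
photographed under UV (bright fluorescing ridges, dark textured substrate).

* **Grayscale.** Rec.601 luma weights (0.299, 0.587, 0.114), rounded to the
  8-bit grid. Achromatic input maps to the channel value exactly.
* **Normalization.** The classic mean/variance normalization: a per-pixel
  affine map on each side of the current mean bringing the image to a
  target mean (default 128 gray levels) and variance (default 2000
  gray-levels²). It is exact, idempotent, and degenerate (constant) images
  raise rather than silently passing all-background downstream. The targets
  are global; block-wise normalization was considered and not adopted
  because the block-wise *binarization* already absorbs slow illumination
  drift.
* **Binarization.** Default is block-wise adaptive Otsu (16 px tiles, each
  thresholded with the Otsu value of a 3-tile window), with global Otsu
  available by configuration. The adaptive default exists because uneven
  ink pressure and substrate interference make any single global threshold
  sever faint ridge segments into spurious termination pairs; with a
  uniform, well-exposed image the two are equivalent. For integer-valued
  (8-bit) images the Otsu threshold is computed as the exact argmax of the
  between-class variance over the 256 candidate thresholds; real-valued
  (normalized) images use a 256-bin histogram.
* **Polarity.** The binary image is flipped, if needed, so 1 always means
  ridge: the ridge class is the darker class for `inked_control` and the
  brighter class for `fluorescent_sample`. The operation is idempotent.
* **Foreground segmentation.** Ridge structure carries energy in a spatial
  band around the ridge frequency. Each pixel is scored by locally averaged
  band-passed energy (difference of Gaussians σ=1/σ=4, averaged at σ=6)
  against 18% of the image's 75th-percentile energy; pixels within 10 px of
  a rejected region are rejected too, because features at the rim of a
  dropout (occlusion, smudge, bare substrate) are truncation artifacts.
  These two constants trade recall against precision on degraded prints and
  are deliberately permissive: stricter settings discard genuine features
  around the cleared valleys of enclosures.

## Ridge analysis

* **Orientation field.** Structure-tensor (doubled-angle least squares)
  orientation per 16 px block; coherence is the normalized eigenvalue gap
  of the summed gradient tensor (1 for stripes, ~0 for isotropic noise).
* **Singular points.** The Poincaré index of each interior block is the net
  rotation of the orientation (mod π) along its 8-neighbor ring, in turns:
  +1 whorl core, +1/2 loop core, −1/2 delta. Blocks adjacent to a
  singularity pick up a half-strength halo, so detections are clustered by
  sign and each cluster is summarised by its extreme-index blocks. When
  several singular points survive, the matcher's (a, b) anchor is the
  highest-|index| core, ties broken by centrality. If no singularity exists
  (an arch), the feature-matrix builder falls back to the minutiae centroid
  and flags it.
* **Skeleton and crossing number.** Thinning uses the Zhang–Suen scheme
  (scikit-image). The crossing number at a skeleton pixel is half the sum
  of absolute differences around its cyclic 8-neighborhood: 1 termination,
  2 ridge interior, 3 bifurcation, ≥4 trifurcation/crossover candidate.
* **Compound structures.** The skeleton is decomposed into node clusters
  (CN ≠ 2) and arm segments. Arms leaving a junction are often mutually
  8-adjacent next to it, so a one-pixel zone around every node is excluded
  when labelling arms (measured lengths are compensated by 2 px per end;
  arms that vanish entirely inside the zones become pseudo-segments with
  centroid distance as length). Rules: two junctions joined by both arms of
  a cycle shorter than `l_eye` → eye (an isolated cycle → lake); a branch
  shorter than `l_spur` from a junction to a tip → spur (branches under
  `l_prune` = 4 px are thinning noise and deleted); a free two-termination
  segment under `l_short` = 15 px → short ridge (island when tiny); two
  adjacent degree-3 junctions bridged by a very short segment with
  through-ridges continuing → crossover.

  `l_eye` defaults to 40 px (~4.5 ridge periods at the default 9 px
  period). The skeleton cycle of an enclosure runs along the annulus
  midline — roughly the lumen perimeter plus 2π times the ridge half-width,
  i.e. lumen + ~14 px — so a bound much tighter than this only admits
  enclosures whose lumen is below the ink-spread blur scale and therefore
  closes into a blob before it can ever be detected.
* **Pores.** Level-3 sweat pores are 4-connected background components
  fully enclosed by ridge pixels with area in [1, 20] px². Pore-sized holes
  are filled before thinning so they do not skeletonize into spurious
  enclosures; pores are excluded from the feature matrix by default
  (level-3 points serve as reference data, not primary identifiers).
* **Filtering.** Points within 10 px of the image border are dropped (the
  pattern is truncated there). Pairs of terminations closer than
  `min_separation` = 12 px are removed as ridge-break artifacts. Opposition
  is judged by distance alone: gating on estimated tip directions was
  implemented and measured, but direction estimates at ragged break tips
  are too noisy — requiring head-on geometry retains more spurious
  endpoints than it saves genuine ones. Finally, minutiae in segments
  rejected by the foreground segmentation, or in blocks with orientation
  coherence below 0.3, are discarded; surviving points carry their block
  coherence as a quality grade.

## Matching

* **Feature matrix.** Rows are the (x, y) coordinates of non-pore minutiae,
  ordered canonically by polar angle about the core and then radius, so the
  matrix does not depend on extraction order. Points within `r_min` = 3 px
  of the core are dropped to keep the distance ratios well-conditioned.
* **Correspondence.** Sample and control points are paired in core-centered
  polar coordinates: candidates must agree in radius within `tol_r` = 10 px
  and angle within `tol_phi` = 0.3 rad, and are accepted greedily by
  ascending polar distance √(Δr² + (r̄·Δφ)²), each index used once. The
  angle tolerance absorbs the small rotations expected between separately
  photographed impressions; no global registration beyond core anchoring is
  attempted, by design.
* **Score.** For pair i, ρ_i is the ratio of squared distances of the two
  points from their own cores, and P = (1/m)·Σ 1/(|ρ_i−1|+1). Each term
  lies in (0, 1], P is their exact arithmetic mean, self-match gives P = 1
  bit-exactly, and uniform radial scaling of a perfect match by s gives the
  closed form P = 1/(|s²−1|+1). Measuring each matrix's distances from its
  *own* core makes the score translation-invariant between independently
  photographed images; rotation of the sample about its core also leaves P
  unchanged. The score is deliberately asymmetric (sample → control); m is
  the number of accepted pairs, and unpaired points do not enter P unless
  the config-gated penalty mode is enabled, in which case they contribute
  zero-valued terms to the mean.

  The two score variants answer different questions. The default form
  measures the geometric agreement of the evidence that *was* paired and is
  by construction insensitive to erasure of minutiae: hiding half of a
  print removes pairs but the survivors still agree, so P barely moves. The
  penalized form charges for missing evidence and is the variant that
  responds to occlusion; the degradation-response study in the acceptance
  suite uses it for exactly that reason, while the separation (sign-test)
  study uses the default form.

## Synthetic data

The generator's purpose is ground truth: every pipeline stage is testable
against known minutiae positions, a known core, and a known rigid transform
between the pair members.

* **Fields.** Zero-pole construction: whorl θ = arg(z−core)+π/2 (index +1,
  concentric flow), loop θ = ½arg(z−core) − ½arg(z−delta) + π/2 (+1/2 and
  −1/2), arch = level sets of a bumped horizontal stratification (no
  singularity).
* **Rendering.** A seeded initial wave — an analytic phase consistent with
  the pattern class (plane wave for arch, concentric for whorl/loop),
  perturbed by Gaussian noise — is iterated four times through a bank of 16
  even-symmetric oriented bandpass (Gabor) kernels at the field
  orientation. The analytic initialisation makes singularity-free patterns
  converge defect-free, so planted edits are the only level-2 events; pure
  noise initialisation would leave metastable dislocations
  indistinguishable from real minutiae and poison the ground truth. The
  final stripe amplitude is equalized by AM demodulation (local envelope
  division) so interference dips cannot binarize into spurious ridge
  breaks. Dominant spatial frequency lands within 15% of 1/ridge_period
  (verified spectrally in the tests).
* **Planting.** Local mask edits with exact bookkeeping: a ridge cut
  (20 px gap — comfortably wider than the 12 px break-merge radius, so the
  two genuine endpoints are never mistaken for a break artifact; both
  endpoints enter the truth), a valley bridge (two bifurcations), an
  enclosure (annulus with a cleared moat in the flanking valleys and a
  through-ridge corridor, so both arms exceed the blur scale; one eye), an
  in-ridge pore. Spur planting is implemented but not in the default mix:
  at a 9 px period a branch short enough to classify as a spur does not
  survive ink-spread blur (it either bridges the valley into a bifurcation
  or is absorbed by thinning); the spur/lake/short-ridge rules are
  exercised by hand-built skeleton fixtures instead. Planted coordinates
  are snapped to the edited pattern's own noise-free skeleton — pure
  geometry of the generated image, independent of any extraction pipeline.
  Sites keep 3.5 ridge periods of separation, stay off the border and the
  core, and enclosures additionally require locally straight flow.
* **Appearance.** The control model applies ink-spread blur (σ 0.7), a
  smooth ±12% pressure field and mild sensor noise to dark-ridge rendering.
  The development model inverts polarity, applies the rigid transform
  (rotation ±4°, translation ±5 px about the image center), scales contrast,
  adds a substrate texture preset (paper: blurred grain plus faint print
  lines; metal: anisotropic streaks; plastic: smooth mottling; glass: low
  texture with glare spots; wood: drifting grain), powder granularity
  noise, optional blurred smudge patches, and opaque occlusion blobs grown
  until the requested image fraction is covered. Default degradation:
  smudge probability 0.05, texture amplitude 0.15, contrast 0.8, occlusion
  fraction 0.1 — a moderately adverse but workable lift, fixed once as the
  study condition. With all knobs at their degenerate values the output is
  exactly the polarity-inverted transform of the rendering.
* **Determinism.** One seed per pair; stages draw from spawned substreams;
  identical parameters give bit-identical artifacts.

### What passing tests do and do not show

The synthetic study establishes internal consistency: the pipeline recovers
what the generator planted, the score separates genuine from impostor
pairs, and degradation lowers the penalized score monotonically. It does
not validate performance on real latent prints: real ridge flow has
curvature statistics, scars, moisture artifacts and sensor physics the
presets do not model, real minutiae densities are higher and less regular,
and the substrate presets are texture archetypes, not physical models.
Level-1 pattern classes beyond arch/loop/whorl (tented arches, double
loops) are not generated.

## Known limitations

* The matcher anchors everything on a single core; prints whose core is
  missing from the captured area degrade to a centroid anchor, which is
  not stable between impressions.
* The radial-ratio score discards angular information; two different
  fingers with similar radial minutia profiles can score high (impostor
  scores around 0.7–0.9 are normal, and identification decisions would
  need a calibrated threshold, which this package deliberately does not
  provide).
* Under the default degradation about one planted minutia in six falls
  under an occlusion blob or its exclusion rim and is unrecoverable by any
  extractor; recall figures on degraded prints must be read against that
  ceiling.
* No oriented (Gabor) enhancement of the grayscale image is performed
  before binarization, by design; heavily degraded regions are segmented
  out rather than restored.
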