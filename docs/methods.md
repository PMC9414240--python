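# Methods

## Problem and model

High-resolution UAV surveys of fruit-tree groves need each tree canopy
located before any per-tree analysis can start. Spectral segmentation alone
fails in olive groves kept with thick plant cover: weeds and canopies are
close in colour, especially in the green band. This package detects olive
canopies by combining weak spectral evidence with the one structural prior a
planted grove reliably offers — the grower's near-regular planting lattice.

The pipeline is:

1. **Radiometric correction.** Raw digital numbers are converted per band to
   at-sensor radiance
   `Lr = a1/(g·te) · V(x,y) · R(y) · (DN − DN_BL)/DN_MAX`, with `V` the
   inverse of a 6th-degree vignetting polynomial in the distance to the
   optical centre and `R(y) = 1/(1 + (a2/te)·y − a3·y)` the row-wise
   sensitivity correction. Radiance becomes the hemispheric–directional
   reflectance factor `HDRF = π·Lr/Ei`, with the incoming irradiance
   `Ei = Edir + Edif` reconstructed from the downwelling light sensor:
   `Es = (Edls/cf)/(w_dif + cos α · sin θi)`, `Edir = Es·sin θi`,
   `Edif = w_dif·Es` (`cf = 0.9057`, `w_dif = 0.167` under clear sky). A
   calibrated reflectance panel imaged before and after the flight anchors
   the absolute level through `f_CRP = π·Lr,CRP/(Ei,CRP·HDRF_panel)`, both
   panel series interpolated linearly in time, giving
   `HDRF_corr = π·Lr/(Ei·f_CRP)`. All arithmetic is 64-bit; rasters on disk
   are 32-bit float. HDRF may exceed 1 (near-specular returns) and is not
   clipped from above; sub-black-level DN is clamped to zero radiance.
2. **Band alignment.** The five sensors are rigidly offset, so each band is
   registered onto the green band by a sub-pixel translation estimated with
   Fourier-domain phase correlation. Registration runs on gradient-magnitude
   images because spectral bands can be strongly *anti*-correlated in
   intensity (NIR vs green over vegetation) while sharing edges. A band whose
   post-warp gradient correlation with the reference stays below 0.2 raises
   an alignment error instead of returning a silent mis-registration.
3. **Colour features.** Only red, green, blue feed the classifiers; they are
   converted to CIELAB so that feature-space distances track perceived
   colour differences. Reflectance is treated as *linear* RGB under sRGB
   primaries and D65 — the point is perceptual linearisation, not
   colorimetric accuracy — and inputs above 1 pass through unclipped.
4. **Vegetation mask.** A local-outlier-factor novelty detector trained on
   the olive+weed labels alone separates vegetation from everything else,
   avoiding the false positives a forced four-class assignment would produce
   on roads, rocks and buildings. Defaults: 100 neighbours, contamination at
   its 0.5 maximum, so the mask keeps only pixels that are vegetation with
   high confidence (at most about half of the in-distribution density
   survives by construction). Neither value is critical downstream; both are
   exposed.
5. **Probability image.** A decision tree (unlimited depth, Gini, fixed
   seed) is fit on olive vs weed. Its hard classification is not trusted;
   each masked-in pixel instead receives its leaf's olive fraction —
   olive-labelled training pixels over total training pixels in the leaf.
   Pixels outside the mask are exactly 0.
6. **Canopy marking.** For every triple (p, k, s) on a regular grid —
   probability threshold p ∈ {0.05,…,0.95} step 0.05, circular-kernel
   diameter k ∈ {5,…,30} step 5, 8-bit segmentation threshold
   s ∈ {5,…,250} step 5; 19·6·50 = 5700 iterations — the chain
   clip/normalise → 3×3 median → circular-mean density → binarise →
   8-connected centroids is run. The Delaunay triangulation of the centroids
   is built and the coefficient of variation
   `Cv = √(N·Σ(l−l̄)²)/Σl` (population σ over mean) of its side lengths is
   computed after recursively pruning boundary triangles with
   inradius/circumradius < 0.1 (slivers along the hull); pruning repeats on
   the newly exposed boundary until stable so no interior holes appear.
   Iterations yielding fewer than three non-collinear centroids are recorded
   as infeasible, not errors. Among iterations whose canopy count lies
   strictly within ±40% of the median count over all feasible iterations,
   the Cv-minimising triple wins; ties break to the lexicographically
   smallest (p, k, s). Cv is dimensionless, so captures with different
   ground sample distances or planting spacings are comparable.
7. **Evaluation.** Ground truth is the olive-labelled pixels dilated by a
   disc of 11 px diameter; its 8-connected components are the positive
   contours. Every predicted point inside a contour is a TP (several hits in
   one contour are all TPs), points outside any contour are FPs, contours
   without a hit are FNs. Hence recall = TP/P with P the contour count —
   TP + FN need not equal P, and recall can exceed 1 when dilated contours
   of adjacent trees merge. Aggregation over captures is micro: counts are
   summed and metrics recomputed from the sums. Omission error is 1 − recall
   and estimation error |PP − P|/P. Cross-validation splits at the capture
   level (labelled pixels of one capture never straddle train and test),
   with fold sizes differing by at most one.

## Synthetic groves

The real 18-capture dataset is available only on request, so a seeded
generator renders the study conditions: canopy discs (radius 5.5 ± 0.6 px)
on a square lattice (spacing 26 px, orientation and positional jitter
σ = 1.5 px configurable) inside a 192×192 px frame — a 7×7 grove at roughly
13 cm/px —, weed discs covering 35% of the non-canopy ground, optional
shadow discs offset from each canopy, and bare soil elsewhere. Per-class
band reflectances put olive and weed close in green and separated mainly in
red/NIR (the hard case); soil is bright and red-shifted; shadows are dark in
every band. Gaussian pixel noise (σ = 0.008) is added per band. Raw DN is
produced by inverting the radiometric model with the default camera
calibration and a DLS record chosen so the brightest surface stays below
sensor saturation, which makes the correction chain testable end-to-end:
correcting the emitted DN recovers the class reflectances to within DN
quantisation (≪1%).

What the generator does *not* emulate: canopy texture and self-shadowing,
irregular canopy outlines, gradients of illumination across a capture,
mis-registration between bands, and labelling error. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms under
the stated geometry and spectra, not field-level accuracy; the field-level
numbers in this repository come from the packaged per-capture counts of the
original campaign, re-aggregated at run time.

A direct probability-image fixture (canopies ~ U(0.7, 1.0), weeds
~ U(0.1, 0.6), background 0) exercises the marking stage alone without
training classifiers.

## Numerical choices

- clip/normalise maps [p, 1] linearly onto [0, 255] with
  round-half-away-from-zero; a constant image at exactly p maps to 0.
- Median and density filters use replicate-edge padding (zero padding would
  bite into boundary canopies); the density kernel contains the offsets
  whose centres lie within k/2, so k = 1 is the identity. The density
  convolution runs via FFT; the brute-force oracle bounds its error at 1e-9.
- Centroids are first image moments of 8-connected components.
- Triangle quality is computed as 8·Area²/(a·b·c·perimeter) =
  inradius/circumradius (0.5 for equilateral, → 0 for slivers).
- The feasibility band (0.6·M, 1.4·M) is an open interval on integer
  counts; M is the median over iterations that produced a triangulation.
- Grid evaluation caches the p-only and (p, k)-only stages across the inner
  loops; a compositional oracle asserts this equals running the five stages
  independently per iteration.
- Degenerate inputs: all-zero probability images make every iteration
  infeasible and marking raises a no-solution error carrying the diagnostic
  surface; collinear centroid sets are infeasibility signals, not
  exceptions.

## Design choices where the design was open

- **Alignment transform family.** Translation-only registration via phase
  correlation on gradients. The sensors' rigid offset at ~180 m altitude is
  dominated by translation; a quality gate turns pathological inputs into
  explicit errors.
- **Lab reference.** Linear sRGB primaries / D65. Any fixed RGB→Lab
  convention serves the purpose (perceptual spacing of the same data on both
  train and predict sides).
- **LOF feature space** is CIELAB, the same space the downstream tree uses.
- **Black level / gain metadata.** The per-channel black-level entries are
  averaged (all 4800 here); gain is ISOSpeed/100 = 2.
- **Tie-breaking and ordering.** Lexicographic (p, k, s) everywhere, making
  every stage bit-reproducible for fixed inputs and seeds.

## Known limitations

- Shadows adjacent to canopies can outscore the canopies themselves in the
  probability image; the marking stage then happily marks the shadow lattice
  (it is just as regular). The generator can render this failure mode
  (`shadow_offset`) for regression work; the fix belongs in the vegetation /
  probability stages, not in the marking objective.
- Square lattices have an intrinsic Cv floor (~0.167: Delaunay mixes unit
  sides and √2 diagonals), and sub-pixel jitter can sit marginally *below*
  that floor; monotone degradation of Cv with jitter is therefore asserted
  from 1 px upward.
- Detection quality is evaluated at canopy level only (point-in-contour);
  no segmentation masks are produced and no IoU is computed.
- The brute-force grid is O(|P|·|K|·|S|) per capture (seconds on the test
  fixtures at 192×192; of the order of a minute on full 1280×960 captures);
  no gradient-based search is attempted.
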