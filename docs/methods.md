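# Methods

## Scope and model

`polarcell` scores two readouts on multi-channel fluorescence images of
single hematopoietic stem cells and daughter-cell doublets:

1. **Polarity** — whether a channel's bright signal is concentrated in a
   boundary-proximal patch rather than spread across the cell, plus the
   direction of that patch; and
2. **Division asymmetry** — whether a marker was inherited unequally by
   the two daughters of a division, from the ratio of summed
   fluorescence.

Both are rule-based classifiers operating on background-subtracted
maximum-intensity projections; no machine learning, no tracking, no 3D
reconstruction.

## The polarity pipeline

Given a (channels × z × y × x) stack:

1. **z-projection**: pixelwise maximum over z, per channel.
2. **Cell mask**: from the across-channel maximum composite. The
   histogram of such an image can be trimodal (background, dim cell
   body, bright polar cap), which defeats bimodal histogram thresholds —
   Otsu's threshold lands between body and cap and segments only the
   cap. We instead estimate the background robustly: the frame is
   background-dominated, so the composite's median and scaled MAD give
   the background level and noise. A noise-free frame (MAD = 0) is
   thresholded exactly at the background level. Otherwise the composite
   is smoothed (Gaussian, σ = 1.5 px) to aggregate photon evidence —
   a body a few counts above background is invisible per pixel but
   unambiguous after smoothing — and thresholded midway between the
   background level and the robust cell-body level (median over an
   initial detection at median + 5·1.4826·MAD); the 50% crossing keeps
   the recovered boundary at the true edge regardless of cell
   brightness. Holes are filled and the largest 8-connected component
   is kept (error if below `min_area_px` = 50).
3. **Background subtraction**: per channel, subtract the median of
   outside-mask pixels, clipped at zero. Idempotent for uniform
   background.
4. **Geometry**: centroid = mean of mask pixel coordinates; major axis
   from second central moments, θ = ½·atan2(2µ₁₁, µ₂₀ − µ₀₂) folded to
   [0°, 180°); boundary-distance map = Euclidean distance to the nearest
   boundary pixel (0 on the boundary itself). The **polarity
   identification zone** is the set of mask pixels within
   `zone_width_px` = 15 of the boundary; the **exclusion area** is the
   closed disk of `exclusion_radius_px` = 10 around the centroid
   (pixel-center membership).
5. **Despeckle**: each channel is median-filtered (3×3,
   `median_filter_px`, 0 disables) before binning. Without it the
   brightest of five k-means bins on a *uniform* noisy channel is
   simply the upper ~10% tail of shot noise; usually its many ≥5-px
   components span the whole cell and the hull rule correctly returns
   nonpolar, but in roughly a quarter of cells only one or two such
   components survive in one sector and the cell is falsely called
   polar — at any signal level, since the effect is scale-free. A small
   median filter (the standard despeckle step of imaging pipelines)
   makes the top bin reflect spatial structure instead of the noise
   tail.
6. **Intensity binning**: globally optimal 1D k-means (`n_bins` = 5) of
   the within-mask intensities. One-dimensional k-means is solved
   *exactly*: optimal clusters are contiguous intervals of the sorted
   values, so a divide-and-conquer dynamic program over unique weighted
   values finds the global optimum deterministically (no seeding, no
   Lloyd iterations). Inputs with fewer distinct values than bins
   collapse to those values and are flagged degenerate.
7. **Cluster extraction**: candidate pixels are those in the
   `top_bins` = 2 brightest bins, with two guards: the dimmest bin is
   never a candidate, and a candidate bin's center must reach half the
   brightest bin's center (a scale-invariant contrast gate that keeps a
   dim cell body out of the candidate set in low-noise images). Two
   bins rather than one because shot noise spreads a homogeneous bright
   cap across adjacent bins — a top-1 rule estimates direction from
   only the brightest-noise subset of cap pixels and loses several
   degrees of angular accuracy. Candidates are grouped into 8-connected
   components; components smaller than `min_cluster_px` = 5 are
   discarded as speckles (strictly smaller: a 5-px component survives).
   Detection runs over the full mask by default (`cluster_scope`), with
   each cluster reporting its fraction inside the identification zone;
   a zone-restricted mode is available.
8. **Polarity rule**: the channel is polar iff the convex hull of all
   surviving cluster pixel centers has empty intersection with the
   exclusion area. The exclusion area is a pixel set, so "overlap"
   means a disk pixel center lies in the closed hull; with integer
   pixel coordinates this discrete criterion is exact and monotone
   (growing the radius can only revoke polarity). A channel with no
   surviving clusters is nonpolar. One joint hull over all clusters
   means bipolar or dispersed signal is scored nonpolar — the intended
   reading of the rule.
9. **Angles**: cluster direction = angle of the vector from the mask
   centroid to the intensity-weighted centroid of the union of cluster
   pixels, reported absolutely (degrees from +x toward +y) and as the
   acute angle to the major axis [0°, 90°]. The polarization angle
   between a channel and the reference channel (tubulin) is the
   absolute difference of their directions folded into [0°, 180°];
   a pair of polar channels with angle ≤ `coloc_angle_deg` = 30 counts
   as copolarized. Angles are undefined (and reported as missing) when
   a channel has no clusters or is nonpolar.

## The paired-daughter assay

The doublet composite is segmented with the same robust-background
threshold; exactly two components ≥ `min_area_px` must be present
(fewer → `NotAPair`, more → `AmbiguousPair`; abutting daughters merge
into one component and are rejected rather than split). After
background subtraction against the region outside both masks, the
sister ratio of each marker is max/min of the two per-mask sums — by
construction label-free, with the brighter daughter recorded. Strict
thresholds classify the division: ratio > 1.5 asymmetric, < 1.2
symmetric, the closed band [1.2, 1.5] indeterminate. How gap-band pairs
enter percentage denominators is not standardized, so summaries are
written under both conventions (indeterminate excluded — the default —
and included). An optional 1-px mask erosion before summation
(`erode_px`, default 0) exists for conservative borders; it is off by
default because component labeling already guarantees disjoint
daughters and erosion breaks exact signal conservation. Co-segregation
of two markers is classified as both-asymmetric-concordant /
-discordant (same or different high daughter), only-first/second-
asymmetric, both-symmetric, or indeterminate.

## Statistics

Counts are aggregated per condition × replicate; class percentages per
replicate (summing to 100 over the included classes) are summarized as
mean ± sample SD (ddof = 1; single-replicate conditions report SD as
missing). Conditions are compared two ways, as is conventional for
imaging cohorts: Fisher's exact test on pooled 2×2 counts — two-sided
by the probability-mass rule, summing hypergeometric probabilities of
all tables no more probable than the observed one (relative gate 1e−7),
degenerate zero-margin tables reported as p = 1 — and an unpaired
two-tailed Student's t test (pooled variance) on replicate percentages.
Significance markers (*, **, *** at 0.05/0.01/0.001) are rendered for
display only.

## The synthetic-data generator

The generator produces the statistical structure the pipeline assumes,
not photorealistic microscopy. A cell is an ellipse (default semi-axes
40 × 32 px on a 128² canvas); each channel distributes `total_signal`
(default 3·10⁵ a.u., giving ≈ 20–75 expected counts per body pixel)
between a spatially uniform component and a **boundary cap** — pixels
within `cap_depth_px` = 12 of the boundary whose angular position from
the center is within `cap_halfwidth_deg` = 35 of the cap direction —
according to `polar_fraction`. Optional speckles (compact blobs of
`speckle_size_px` pixels, `speckle_signal` a.u. each) are drawn from
the uniform budget, so the noiseless within-mask sum always equals
`total_signal` exactly. Noise is Poisson on signal + background
(default background 8 a.u.), reflecting photon-limited fluorescence;
a noiseless mode and an additive-Gaussian extension exist. Ground
truth marks a channel polar when `polar_fraction` exceeds the
generator's polar threshold (0.5, a documented generator parameter —
the source material defines no generative notion of "polar").

Doublets are two disjoint ellipses on a 128 × 192 canvas; the low
daughter receives `total_signal` (default 5·10⁴) and the high daughter
`ratio ×` that, per channel, so the noiseless measured ratio is exact.
Truth classes follow the same >1.5/<1.2 rule. Cohort generators
randomize geometry (semi-axes a ∈ [34, 44], b ∈ [28, 34], orientation,
cap directions), assign replicates round-robin, and are reproducible
from a single seed.

Calibration notes, decided once by detectability under the pipeline's
own rule rather than fitted to any dataset: `cap_depth_px` = 12 (not
the analysis zone width 15) keeps a cap's convex hull clear of the
10-px exclusion disk even on the smallest cohort cells — with depth 15
and semi-minor axis 28, the hull chord grazes the disk and the ground
truth would be undetectable by construction; cohort polar fractions are
drawn from [0.6, 0.9]. Angle-recovery cohorts use near-circular cells
(36 × 34): on elongated cells the angular-wedge centroid is biased by
several degrees toward the major axis, a property of the estimator
(see limitations), not of the noise.

What the generator does **not** emulate: point-spread blur, chromatic
shifts, uneven illumination, out-of-focus light, cell-shape
irregularity, touching cells, or any temporal dynamics. Passing
recovery tests therefore demonstrates the correctness of the decision
rules and estimators under the assumed statistics, not robustness to
every artifact of real microscopy.

## Numerical choices

- Coordinates: pixel-centered integer lattice, origin top-left, x along
  columns, y along rows; directions in degrees from +x toward +y, mod
  360; axes mod 180; direction-vs-axis angles folded to [0°, 90°].
- The hull-vs-disk test uses exact geometric predicates (shapely) on
  integer pixel centers; the test suite checks it against an
  independent half-plane oracle with 100% required agreement.
- k-means ties at bin midpoints break toward the lower bin; bin centers
  are strictly ascending after deduplication.
- Fisher p-values use scipy's hypergeometric pmf over the table
  support; the suite checks them against exact rational enumeration to
  1e−10.
- All randomness flows through `numpy.random.default_rng` seeds
  recorded in every output; reruns with identical config + seed are
  byte-identical (outputs contain no timestamps).
- Degenerate inputs: constant images raise `NoCellFound`; masks < 3 px
  raise `DegenerateMask`; a zero daughter sum yields `UndefinedRatio`
  (flagged, excluded from summaries); a channel with no clusters is
  scored nonpolar and flagged rather than dropped.

## Verification scales

The test suite and `scripts/acceptance.py` run at desk scale, chosen to
keep the full suite under a minute of compute while leaving recovery
margins wide: 200-cell mixed cohorts (60% polar) plus 60-cell noiseless
cohorts for polarity; 90 cells across programmed channel offsets
{0°, 45°, 90°} for angle recovery; 300 doublets per programmed ratio
{1.0, 1.6, 2.0}; 220 randomized hull/disk configurations; 100 random
vectors for k-means optimality; 1000 random 2×2 tables for Fisher
exactness.

## Known limitations

- The angular-wedge direction estimator is biased on elongated cells
  (cap centroids pull toward the major axis by up to ~10–15° for axis
  ratios ≈ 1.25 at 35° half-width); polarization angles on
  near-circular cells are accurate to a few degrees.
- Per-pixel Poisson noise with a homogeneous cap is an idealization;
  structured texture (real tubulin filaments, vesicles) may bin
  differently.
- The mask threshold assumes the frame is background-dominated (cell
  under ~half the frame) and a single cell (or exactly two daughters)
  per image; crowded fields need upstream cropping.
- Cells with `polar_fraction` → 1 have an essentially invisible body;
  segmentation then recovers only the cap, and the polarity rule is
  evaluated on cap geometry alone.
- The gap band [1.2, 1.5] of sister ratios is genuinely unclassified;
  downstream percentages depend on the chosen denominator convention,
  which is why both are emitted.
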