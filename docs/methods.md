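# Methods

## The problem

Counting and measuring cells and colonies from digital images —
tumorspheres in brightfield, bacterial colonies on agar plates, stained
clonogenic-assay colonies — is a bottleneck in quantitative cellular
assays.  Plain intensity thresholding fails when objects barely differ
from the background (unstained spheroids, agar colonies) or when the
illumination is uneven.  `colonyedge` segments by *edges* instead: an
object does not need to differ from the background in absolute
intensity, only to have a boundary where intensity changes quickly.

## The pipeline

The detector is a fixed-order composition of classical operations, each
exposed as a named, parameterised, individually skippable stage:

1. **Background subtraction.**  A smooth background is estimated by a
   rolling ball (grayscale opening with a ball-height structuring
   element of radius *r*, Sternberg's construction) and subtracted,
   flattening illumination trends whose spatial scale exceeds the ball.
   A sensible starting radius is the average colony radius.  For
   *r* > 10 the opening is computed on a block-minimum-reduced image
   (factors 2/4/8 by radius band) and the background re-expanded by
   bilinear interpolation — the standard shrink speed-up; the exact
   opening is available via `shrink=1` and is what the oracle tests
   check.  With `light_background` the image is inverted around the
   depth ceiling first and re-inverted after.
2. **Sharpen, enhance, find edges.**  The 3×3 sharpening kernel
   (centre 12, neighbours −1, normalised by 4) steepens boundaries;
   linear contrast enhancement saturating 0.2 % of pixels stretches the
   range; the Sobel magnitude √(Gx²+Gy²) converts boundaries into
   bright ridges.  All convolutions replicate edge pixels at the
   border, keeping border-object areas stable.
3. **Smooth and binarize.**  A Gaussian blur (kernel truncated at 3 σ)
   suppresses pixel noise in the edge image, then an automatic global
   threshold — iterative intermeans (IsoData), pixels strictly above
   threshold becoming foreground — yields the binary edge mask.  The
   threshold's histogram is taken over the image's depth range: edge
   magnitudes beyond the ceiling count as saturated, exactly as they
   would on fixed-depth data.  This matters: a handful of extremely
   strong edges would otherwise inflate the upper class mean and push
   the threshold above the rings of the faintest objects.  A constant
   image binarizes to all-background.
4. **Close and fill.**  Morphological closing (3×3, dilation then
   border-aware erosion, extensive by construction) seals small gaps in
   the edge rings; hole filling turns every background region not
   4-connected to the border into foreground, converting closed rings
   into solid objects.  A second closing/filling pass bracketed by a
   *Maximum* (disk dilation) and a *Minimum* (disk erosion) rank filter
   bridges larger gaps: the dilation pulls broken edge ends together so
   they close and fill, and the erosion returns objects towards their
   original size.  The digital disk of radius *r* contains pixels with
   centre distance ≤ *r* + 0.5.
5. **Denoise and segment.**  *Remove outliers* replaces any pixel that
   deviates from its disk-neighbourhood median by more than a threshold
   (default 50 on the 8-bit scale) in one polarity; on a binary mask
   with polarity `bright` this deletes foreground blobs smaller than
   roughly half the neighbourhood while leaving solid objects intact.
   Touching objects are then split by the binary watershed: the
   Euclidean distance map (frame border counts as background) is
   flooded from its regional maxima, with maxima of dynamics ≤ 0.5
   (height above the saddle towards a higher maximum) merged to avoid
   double-seeding from digitisation plateaus; a one-pixel divide line
   between basins becomes background.  The watershed is reliable only
   for convex, roughly circular regions — for elongated cells the
   stage should be disabled, which is a one-call toggle.
6. **Filter and measure.**  Connected components (8-connectivity,
   labels in raster-scan order of first pixel) are measured and then
   filtered by calibrated area, circularity, and optionally edge
   contact.  Area is the pixel count × calibration²; perimeter is the
   Freeman chain-code length of the outer contour traced through pixel
   centres (orthogonal step 1, diagonal √2) × calibration; circularity
   is min(1, 4π·area/perimeter²).  Intensity statistics are taken over
   the object's pixels of the *original* image (measurement redirect),
   not of the processed mask.

Presets encode the published parameter sets for the three assay
classes (see `colonyedge.pipeline.preset`); a `threshold_baseline`
preset (background subtraction → global threshold → watershed) stands
in for the plain thresholding workflows the edge method is compared
against.

## Numerical and convention choices

* Pixels are processed as float64 regardless of input depth;
  quantisation happens only on export.  `white_level` records the
  nominal depth ceiling (255 or 65535) for the operations that need it
  (sharpen clipping, contrast enhancement, threshold saturation).
* Foreground = object everywhere in memory; the "black colonies on
  white background" display polarity is applied only when writing mask
  files.
* Chain-code perimeter overestimates a smooth circle's circumference by
  ≈5.5 % (a known property of 8-neighbour chain codes), so digital-disk
  circularity converges to ≈0.907 rather than 1.0; elongated bars score
  far lower, which is what the circularity filter relies on.  A
  single-pixel object has no chain steps; its circularity is defined
  as 1.
* Holes count towards area but not perimeter; pipelines fill holes
  before measuring, so in practice measured objects are solid.
* IsoData is used for `make_binary` (the classical iterative
  intermeans); for integer-valued data the iteration runs on the exact
  values, for float data on a 256-level quantisation.  Otsu can be
  swapped in by registering a different convert stage if ever needed.
* Watershed flooding order and the divide-line carving (a basin pixel
  with an 8-neighbour in a lower-numbered basin becomes background)
  are deterministic, making the whole pipeline a pure function of
  (image, config): reruns produce bit-identical masks and tables.

## The synthetic scenes

`colonyedge.synthetic_fixtures` renders scenes with exact analytic
ground truth so every stage is testable without microscope data.
Objects are anti-aliased ellipses (≈1 px edge softness; coverage 0.5 on
the analytic boundary, so thresholding the clean image at half
contrast recovers π·a·b within 5 % for radii ≥ 5 px) over a uniform
background, plus a linear illumination gradient, an optional radial
vignette, Gaussian sensor noise with 8-bit quantisation, random walk
specks of 1–4 px, and scratch lines.  Named scenarios fix the study
conditions:

* `tumorsphere_like` — 800×640, twelve dark ellipses with semi-axes
  12–60 px (aspect ≤ 1.35), contrast 15–40 on 8-bit, ~10 % illumination
  gradient plus a mild vignette, noise σ = 2, a few debris specks;
  calibration 1.3 µm/px (a 5× brightfield objective scale).
* `bacterial_like` — 512², 22 bright disks of radius 2.5–6 px on a dark
  plate, five bright scratch lines and specks, noise σ = 2.
* `clonogenic_like` — 640², thirty dark stained colonies of radius
  5–14 px at high contrast (60–110).
* `touching_pairs` — one fused disk pair per scene, radius 14–20 px,
  centre distance 1.2–1.6 × radius, composited by maximum coverage so
  the union has no intensity ridge — the hard case for the watershed.
* `artifact_stress` — eight genuine bright colonies among ≥ 500
  sub-threshold specks and five scratches.

What these scenes do *not* model: texture inside colonies, defocus
blur, Nomarski shading, compression artifacts.  Passing tests
therefore demonstrate the pipeline's geometric and photometric
behaviour, not robustness to every optical effect in real micrographs.

## Evaluation protocol

Detected objects are compared to a reference table by greedy centroid
matching: references in descending area order each claim the
largest-area unassigned detection whose centroid lies within
max(reference equivalent radius, a distance gate, default 10 px).
This operationalises the manual matching convention with its two
explicit rules: a fragmented colony is represented by its largest
fragment (the rest become extra colonies, numbered after the last
reference id), and an unsplit pair of touching colonies matches the
larger reference (the smaller counts as undetected).  Agreement is
summarised by ordinary least squares of detected on reference measure
(slope, intercept, R²) plus the mean absolute per-pair deviation, and
`replicate_average` averages repeated runs per object (deterministic
pipelines give standard error 0).

## Behaviour under the study conditions

On the `tumorsphere_like` scene the tumorsphere preset recovers all
twelve objects with an area fit of slope ≈ 1.04–1.08 and R² ≥ 0.996
(computed by `scripts/acceptance.py`).  Areas carry a small outward
bias that grows with edge contrast: filling measures to the outer side
of the super-threshold edge ring, and the preset's Minimum 3 /
Maximum 2 pair shaves one pixel back, leaving ≈ +0.4 px (faint) to
+1.6 px (strong) of radius; worst-case per-object error is ~14 %.
Fused pairs split in ≥ 95 % of seeded scenes; with the watershed
disabled each pair is counted once.  The despeckling configuration
removes every speck and scratch on the stress scene with zero false
positives.  On the noisy bacterial scene the preset's published
minimum size of 2 px² is below the size of coherent noise blobs, so
recall is perfect but precision is poor — on real, cleaner plate
photographs the same filter is adequate; raising `min_size` or the
outlier-removal radius restores precision on noisy inputs.  The
clonogenic preset's asymmetric Maximum 1 / Minimum 4 shrinks crisp
synthetic colonies by ≈ 1 px of radius (area slope ≈ 0.85) and drops
the smallest below the 50 px² size cut; it is tuned for the softer
edges of real stained-colony photographs.

## Problem sizes

Default test and acceptance scenes are 512²–800×640 px with 8–30
objects; the batch demonstration uses twelve 512² images, which two
successive runs process to byte-identical CSVs in a few seconds each.
These sizes exercise every stage at realistic object scales while
keeping the full suite fast.

## Known limitations

* The watershed over-splits elongated or branched shapes; disable it
  for such samples (the toggle exists precisely for this).
* Very low-resolution or defocused edges (no sharp grayscale change)
  defeat edge detection itself.
* The bacterial preset's tiny size filter assumes clean plate images;
  see above.
* Volume is not computed: no defensible formula exists from a single
  2-D projection without a sphericity assumption, so it is left out.
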