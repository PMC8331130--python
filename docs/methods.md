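# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `gridfree`, and what the synthetic benchmark does and
does not demonstrate.

## Pixel classification

The POI extractor assumes objects differ from background in *color
composition*, not merely brightness: the 12 default indices (PAT, DIF, ROO,
GLD per channel) are ratios and differences of channels, i.e. chromaticity
features. PCA is computed on the correlation matrix — columns are
standardized to zero mean and unit variance first — because raw channels
live on 0–255 while index ranges vary per image and can be negative; with
covariance, a wide-range column would dominate regardless of information
content. Eigenvalues below 1e-10 are treated as zero; eigenvector signs are
fixed by making each loading vector's largest-magnitude entry positive, so
repeated runs are bit-identical. Zero-variance columns are dropped with a
warning; an all-constant block is an error. When an index denominator is
exactly zero the index value is defined as 0 — this affects only pure-black
and similar edge pixels and keeps the PCA finite. The index registry lets a
user swap any formula without touching downstream code.

Component blending operates on the 0–255 *rescaled gray* fields rather than
raw scores. Raw-score blending would let whichever block has larger score
variance dominate at every weight; on gray fields the weight is a true
convex interpolation between two images the user has seen. Weights snap to
the 0.02 grid (with a warning) so a parameter file always round-trips.

Gray rescaling maps min→0 and max→255 with half-up rounding; a constant
field becomes all zeros (with a warning) since it carries no contrast.

K-Means runs on the single gray value per pixel, so the problem is
one-dimensional over at most 256 distinct levels. The optimal 1-D solution
partitions sorted values contiguously, so the solver is an exact weighted
dynamic program (O(levels²·k), microseconds at these sizes) rather than
iterative Lloyd refinement: deterministic, seed-free, and globally optimal
for every k — restarts and initialization heuristics have nothing left to
do. The `seed` argument is retained in the API but inert. Clusters are
numbered by ascending mean gray value. If `k` exceeds the number of
distinct levels it is reduced with a warning.

## Divide-and-combine segmentation

All connectivity is 8-connected, including flood-fill components, boundary
definitions and geodesic reassignment. A segment's size is summarized by
pixel area and bounding-box diagonal `√((r_max−r_min+1)² + (c_max−c_min+1)²)`
— the diagonal was chosen over the maximal inter-pixel chord because it is
cheap, monotone with the bounding box, and serves the same outlier-flagging
purpose on the area/size scatter.

Removal below the lower bounds is permanent. The mean reference area for
split-count estimation is the mean over segments currently inside both
bound pairs ("correctly segmented" ones); if none qualify, the mean over
all segments is used with a warning. The estimated object count of a fused
region is `round(area/mean)`, half-up, floored at 2.

**Watershed marker search.** The distance-transform maxima are searched in
a square window of area equal to the current *search region*, which starts
at the mean area and halves per iteration (the first shrink removes exactly
one half of the mean area) until the marker count reaches the estimate or
the region reaches one pixel; side length is `round(√region)`, and a
plateau of equal maxima yields one marker at the plateau pixel nearest its
centroid. The window sweep decides *how many* markers exist — fewer than
two means the segment is left unchanged and flagged `unsplittable`. *Which*
pixels become markers is decided separately by topographic prominence
(persistence of each distance-map peak above its saddle toward a deeper
peak): the discrete distance transform carries sub-pixel wobble along a
single elongated object's ridge, producing window maxima that are not
object centers, and depth- or spacing-based tie-breaks were found to pick
those bumps on tangent ellipse pairs (asymmetric cuts, over-splits).
Prominence ranking chooses the true second center in every such case
because an object center always sits several pixels above the neck saddle
while ridge wobble sits a fraction of a pixel above its surroundings. The
watershed then floods the negated distance map from the chosen markers,
restricted to the segment.

**Boundary shrinkage** peels all pixels with a background 8-neighbor, one
layer per iteration, until the remnant splits into two or more pieces or
satisfies the upper bounds (if it vanishes first, or re-enabling would just
restore the parent, the segment is flagged `unsplittable`). Peeled pixels
are re-enabled by simultaneous geodesic dilation from the remnant pieces —
each peeled pixel joins the piece it reaches first, ties going to the
lower-numbered piece — so the children exactly partition the parent.
Watershed is tried first and shrinkage is the fallback: the watershed
handles smooth-rimmed adjacency, shrinkage handles dented rims, and a fixed
order keeps the pipeline deterministic. Oversized children re-enter the
same queue; a child identical to its parent stops the recursion.

**Expansion-merge.** A split fragment below the lower bounds grows back
toward the sibling sharing the longest border (counted as 8-adjacent pixel
pairs, restricted to pairs crossing shrinkage-disabled pixels when a
disabled set exists); it merges into that sibling if the union meets the
lower bounds, and is deleted when isolated or still short. Final ids are
dense, in raster order of each segment's first pixel.

## Morphometry and scaling

Length is the maximum Euclidean distance between *pixel centers* of
boundary pixels (a 1×5 pixel run has length 4.0); the farthest pair is
found on the convex hull with exact integer squared distances, ties going
to the first pair in raster order, with a full pairwise fallback for
degenerate (collinear) boundaries. Width is the extent of all boundary
pixels projected perpendicular to the length axis — equivalent to the
longest perpendicular chord for convex shapes and a deterministic
generalization for concave ones. The center-to-center convention
undercounts a dimension by roughly one pixel of extent, a ~2 % effect at
the benchmark's object sizes.

A scale reference contributes only its total pixel count: `mm²/px` is the
known area over the counted pixels, and linear measures convert by the
square root of that ratio — the unique dimensionally consistent extension,
since only the area ratio is defined. Batch mode has no reference
selection, so batch outputs remain in pixels.

## Synthetic scenes: what they emulate and what they do not

The generator emulates the package's target photographs: elliptical kernels
of one variety scattered on a contrasting sheet. Defaults, chosen once as
the realistic condition:

* **Kernel color** (120, 78, 40) on background (235, 235, 235): a chromatic
  kernel brown on near-white paper (a "black" preset would use background
  ≈ 20). Chromaticity matters: the index families cannot separate a
  *neutral* dark gray fill from neutral background — that is a property of
  ratio indices, not an implementation defect, and real kernels are
  chromatic.
* **Semi-axes** Gaussian (14, 9) ± (1.0, 0.6) px, clipped at 3 px: area
  CV ≈ 10 %, matching the single-digit length/width CVs of a single-variety
  seed lot. Size spread is what makes threshold-driven splitting possible
  at all: the upper bar must fit between the largest single and the
  smallest fused pair.
* **Noise** σ = 8 gray levels per channel, i.i.d.: sensor noise scale.
* **Touching pairs** overlap 1.5 px along the line of centers so rendered
  pairs are genuinely 8-connected; contested pixels belong to the nearer
  center (in normalized ellipse coordinates) and true ownership is
  recorded.
* Specks are kernel-colored disks capped at 20 % of the smallest object's
  area; the reference disk defaults to a penny-sized 285 mm².

Placement is rejection sampling on bounding circles with a 3 px minimum
separation and a 10,000-attempt cap per object (a denser request raises a
generation error suggesting a larger canvas).

The scenes do *not* model perspective skew, uneven illumination, shadows,
specular highlights, wrinkled or non-elliptical kernel outlines (a
sinusoidal-rim mode exercises the shrinkage path but is not photorealism),
or kernels resting at an angle (the real-world cause of visible-width
underestimation, for which no correction exists here). Passing the
benchmark therefore demonstrates the correctness of the algorithms under
their stated assumptions — contrast, no overlap beyond tangency,
single-variety sizes — not robustness to photography artifacts.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use canvases of 900²–2400² px
for 100–1000 objects (≈ 14 % cover), ten 200-object scenes with 20 % of
objects in tangent pairs for the splitting benchmark (upper area bar at
1.5× the observed median segment area, lower at 0.2×, mirroring how a user
reads the bars off the area/diagonal scatter), and one hundred 5–20 px
semi-axis ellipses with a 50 px reference disk for morphometry. Component
labeling is cross-checked against a hand-written union-find on 200 random
64×64 masks, and the 1-D K-Means against exhaustive contiguous partition
search at n = 30, k = 3.

## Known limitations

* Only 8-bit RGB input is modeled; 16-bit input is linearly rescaled and
  grayscale replicated, with warnings.
* The splitter's count estimate is an area quotient; fused groups whose
  sizes deviate strongly from the in-bounds mean can be over- or
  under-split, and the result is then only as good as the user's bounds.
* A fused pair whose joint area stays below the upper bar is never flagged,
  and a legitimately oversized single above it will be force-split; both
  are consequences of purely threshold-driven suspicion.
* Segments flagged `unsplittable` are retained and logged rather than
  guessed at.
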