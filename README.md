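# gridfree

Headless counting and measuring of seeds — and other small, irregularly
placed, possibly touching objects such as colonies, spores or cells — in
ordinary RGB photographs.

Grain traits such as kernel count, length, width and area are core yield
components, and counting or calipering thousands of kernels by hand is the
bottleneck. Photographing kernels scattered on a contrasting sheet is easy;
the hard parts are (1) separating kernel pixels from background and noise
without hand-picking a color index, and (2) separating kernels that touch.
`gridfree` addresses both with a two-level filter followed by a
divide-and-combine segmentation, and converts pixel measurements to
millimeters using any in-scene object of known area.

## Method

**Pixels of interest (POI).** The image's `h·w` pixels form a feature matrix
with 15 columns: the raw R, G, B channels plus 12 color indices — four
families per channel, with `Y` the cyclic successor of `X` and `Z` the
remaining channel:

    PAT_X = X/(X+Y)      DIF_X = 2X−Y−Z      ROO_X = X/Y      GLD_X = (X−Y)/(X+Z)

PCA runs on the RGB block and the index block separately, on the
**correlation** matrix so column scales do not matter. Component score
fields are rescaled to 0–255 gray images; a gray RGB component may be
blended with a gray index component by a weight on a 0.02 grid. The chosen
gray image is clustered by 1-D K-Means (k ≤ 10; solved exactly over the
≤ 256 gray levels), and the user-selected clusters become the binary POI
mask.

**Divide and combine.** 8-connected components give initial segments, each
summarized by its pixel area `A` and bounding-box diagonal
`D = √(h² + w²)`. The user sets bounds `[A_min, A_max]` and
`[D_min, D_max]`; segments below the lower bounds are removed permanently,
segments above the upper bounds are suspected fusions and are split:

* *Watershed:* markers are maxima of the Euclidean distance transform,
  searched in a square window whose area starts at the mean in-bounds
  segment area and halves until `round(A/mean)` markers appear (markers are
  ranked by topographic prominence); the negated distance map is flooded
  from them.
* *Boundary shrinkage* (fallback for dented rims): pixels with a background
  8-neighbor are peeled layer by layer until the remnant separates, then
  peeled pixels are re-assigned to the nearest remnant piece.
* Undersized fragments merge into the sibling sharing the longest border,
  or are deleted.

**Measurements.** Length is the longest distance between boundary-pixel
centers; width is the boundary extent perpendicular to that chord. With a
reference object of known area (only its total area matters), areas scale
by `mm²/px` and lengths by its square root.

## Worked example

`gridfree` ships a ground-truthed scene generator. Render 12 brown kernels
plus a 285 mm² reference disk (a US penny) and segment the photo:

```bash
gridfree preview --input seeds.png --export out/        # PC thumbnails + clusters
gridfree segment --input seeds.png --export out/ \
    --pc idx:1 --k 2 --clusters 0 --area-min 20 --diag-min 4 \
    --ref-id 12 --ref-area-mm2 285.0
```

which prints `13 segments -> out/seeds_measurements.csv` (12 kernels + the
reference) and writes, per segment:

```
 id  area_px  diagonal_px  length_px  width_px  area_mm2  length_mm  width_mm
  1      338        31.62      26.93     15.41     19.20       6.42      3.67
  2      427        34.41      28.79     18.37     24.26       6.86      4.38
  3      438        34.21      27.86     19.67     24.89       6.64      4.69
...
 12     5016       113.14      79.88     79.66    285.00      19.04     18.99
```

Row 12 is the reference disk (5016 px ↦ 285 mm² fixes the scale at
0.238 mm/px); the kernels come out about 6.5 mm long and 4 mm wide —
wheat-sized, as generated. Alongside the CSV the run writes an overlay PNG
with red id-labelled boxes, a 16-bit label mask, an area-versus-diagonal
scatter plot with the threshold bars, and the parameter JSON that replays
the run bit-for-bit. `gridfree batch --input dir/ --params pilot.json
--export out/` applies one parameter file to a directory (pixel units only:
batch mode has no reference selection).

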