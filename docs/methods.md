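# Methods

## The measurement model

`ihcmorph` treats a brightfield IHC scan as a two-stain absorption image:
hematoxylin marks nuclei and absorbs mostly red light; DAB marks the
antigen (here a perinuclear ER-stress marker) and absorbs mostly blue.
Two per-pixel score maps are derived from the normalized RGB raster:

* `nuclear_map = 1 − L(red)`
* `signal_map  = 1 − L(blue)`

with `L(x) = log(1 + kx)/log(1 + k)`, `k = 255` by default.  `L` is a
strictly increasing bijection of [0, 1] for any `k > 0`, so thresholding
the enhanced map is order-equivalent to thresholding the raw channel; the
enhancement only spreads the dark (stained) range so that Otsu's criterion
sees a well-separated foreground mode.  The inversion `1 − L(x)` is used
instead of optical density `−log(x)` because it is bounded and finite at
saturated dark pixels, which 8-bit scans do contain.  The green channel is
not used: for this stain pair it carries the least stain-specific
contrast.  No stain-vector unmixing (color deconvolution) is attempted;
the two maps are channel proxies, not stain concentrations.

## Segmentation

1. Threshold `nuclear_map`: Otsu by default, or a fixed value in [0, 1]
   for batch-to-batch comparability.  A contrast-free map yields an empty
   mask and a warning, not an error.
2. Fill holes (chromatin texture must not punch holes in the area used as
   a ploidy surrogate).
3. Optionally split touching nuclei: watershed on the negated Euclidean
   distance transform, smoothed with a Gaussian of σ = 1 px.  Seeds are
   the h-maxima of the smoothed transform with prominence ≥ 2 px.  The
   prominence criterion matters: two overlapping round nuclei create a
   genuine third regional maximum at their waist (for disks of radius r
   overlapping at 1.5 r its prominence is under 1 px), so a plain
   minimum-separation rule over-seeds no matter the separation chosen,
   while true nucleus peaks have prominence on the order of the nucleus
   radius.  Prominence 2 px sits between the two regimes down to the
   smallest nuclei the default area filter admits (≈ 4 px radius).
4. Remove objects below `min_nucleus_area_px` (default 50 px — about the
   smallest plausible nuclear cross-section at typical 20–40× scan
   resolution) and above `max_nucleus_area_px` if set.
5. Drop objects touching the image border by default: their area is
   censored and would bias the area distribution downward.
6. Relabel 1..N by raster-scan order of each object's first pixel, making
   label numbering deterministic.

Connectivity is 8-connected throughout, the standard choice for blob-like
nuclei.

## Perinuclear rings

The cytoplasmic region of interest of nucleus *i* is
`{p : nuclei(p) = 0 and d(p, nucleus_i) ≤ w}` with ring width `w = 7` px
by default, the value the underlying staining protocol was designed
around.  Distance is Euclidean by default (isotropic band; a city-block
variant is available for sensitivity checks).  Contested pixels between
adjacent nuclei go to the nearest nucleus, with exact-distance ties broken
toward the smaller label.  The implementation computes, per nucleus,
integer squared distances from a distance-transform nearest-pixel index
restricted to the nucleus's padded bounding box, and keeps a running
strict minimum in ascending label order; because all comparisons are on
exact integers, the result is pixel-identical to an exhaustive per-pixel
scan, which the test suite verifies on randomized masks.  A nucleus fully
enclosed by neighbors gets an empty ring; it keeps its area but its ring
signal is undefined and excluded from signal summaries (the excluded count
is reported).

## Measurement and statistics

Per nucleus: pixel area (and `area_px × pixel_size_um²` when a pixel size
is supplied — it is metadata, never assumed), centroid, ring pixel count,
ring mean of `signal_map`, and the integrated (summed) signal.  Both
intensity statistics are always computed; the mean is the default
reporting choice because it is size-independent, while the integrated
value can matter when total per-cell signal is of interest.  Group
summaries give mean ± SEM (SEM = sd/√n, undefined for n < 2) and
30-bin equal-width histograms.  Group comparison is a two-sample
pooled-variance Student's *t* test with a one-tailed alternative stated
about the first group; Welch's correction is available by flag.  No
multiple-testing correction is applied; comparisons are per-pair.

## Synthetic scenes

The generator renders each nucleus as a rotated ellipse (center-in-ellipse
rasterization; semi-axes `r/(1−e²)^¼` and `r(1−e²)^¼` so the analytic area
is `πr²` at any eccentricity) filled with hematoxylin, plus a perinuclear
DAB shell obtained by growing both semi-axes by the shell thickness
(default 5 px).  Channels follow Beer–Lambert:
`I_c = white_c · 10^(−c_h·od_h[c] − c_d·od_d[c])`, with unit-norm OD
vectors `od_h = (0.80, 0.52, 0.30)/‖·‖` (red-dominant) and
`od_d = (0.10, 0.45, 0.888)/‖·‖` (blue-dominant).  These are idealized
low-cross-talk vectors, not empirical stain spectra: real DAB absorbs
appreciably in red, and with strong chromogen that cross-talk darkens the
shell enough for a global threshold to annex it into the nucleus.  Keeping
cross-talk low makes each stain readable in its own detection channel,
which is the regime the channel-pairing analysis is designed for — and a
known limitation for heavily DAB-loaded real tissue, where a fixed
threshold or ROI pre-selection is advisable.

Gaussian noise (default sd 0.02 in transmission units) is added in
transmission space and clipped to [0, 1]; rendering is deterministic given
the scene seed.  Random fields place nuclei by rejection sampling with a
minimum center separation (default: two nucleus-plus-shell radii, i.e.
well-separated; pass 0 to exercise watershed splitting); the default field
is 1024 × 1024 with 100 nuclei of radius 10–16 px, a dense but separable
tissue mimic.  Per-cell hematoxylin is drawn from U(0.7, 1.0) and DAB from
U(0.3, 0.9), spanning weakly to strongly stained cells.  The
population-pair generator shares one layout between a "parental" and a
"hyperploid" scene and scales hyperploid radii by √(ploidy ratio) and DAB
by the signal ratio, mirroring the biology being measured: genome doubling
roughly doubles nuclear cross-section, and ER stress raises the
perinuclear marker.

What the generator does **not** emulate: tissue texture, stromal
architecture, uneven illumination, out-of-focus blur, overlapping nuclei
in z, or empirical stain spectra.  Passing tests therefore show the
algorithm is correct and self-consistent under idealized staining; they do
not certify performance on real tissue, where stromal/malignant
discrimination in particular remains the user's job (an ROI mask input is
accepted for that).

## Numerical and design choices

* All intensities are normalized to [0, 1] by the source white level
  (255 / 65535 / 1.0) immediately on reading, so `k`, thresholds, and map
  values are bit-depth independent.
* Ring distances are compared as exact integers (squared Euclidean or
  city-block counts); no floating-point distance ties exist.
* Label numbering, CSV row order, and float formatting (shortest
  round-trip repr) are all deterministic; re-running `analyze` on the same
  input reproduces the CSV byte for byte, and re-running `simulate` with
  the same seed reproduces the TIFF byte for byte.
* Degenerate inputs: empty segmentation is a success with n = 0 and a
  warning; an empty record list summarizes to an error naming the empty
  group; SEM is undefined (null) for n < 2.
* Problem sizes in the test suite and acceptance script (100 random masks
  ≤ 128 × 128 for the exhaustive ring oracle; one 1024 × 1024 field of
  100 nuclei; 100-cell population pairs) were chosen as the smallest
  scales at which the geometric and statistical claims are meaningfully
  exercised.

## Known limitations

* The channel-proxy stain separation saturates when both stains co-locate
  densely; quantitative DAB comparisons across batches should use fixed
  thresholds and identical scanner settings.
* Watershed splitting assumes roughly convex nuclei; strongly lobed or
  densely clumped nuclei may remain merged or over-split.
* Nuclear area is a ploidy *surrogate*: section thickness, cutting plane,
  and fixation all shift the area distribution, so only within-batch
  comparisons are meaningful.
* Whole-slide images must be tiled by the user; the tool processes flat
  rasters that fit in memory.
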