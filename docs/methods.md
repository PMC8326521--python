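# Methods

## Imaging model and assumptions

The pipeline assumes the acquisition geometry of a fixed-chip flow channel:
a static scene (constant illumination, fixed optics, fixed chip) with islets
as the only moving objects, flowing predominantly along one image axis (+x).
Under these assumptions the background can be captured once and foreground
recovered by subtraction; no rolling background model or illumination-drift
correction is attempted. Physical scale enters through a single factor
δ (µm/px), measured from a scale marker embedded in the chip (e.g. a 1 mm
marker spanning 460 px gives δ ≈ 2.174 µm/px). Frame rate is carried as
metadata only; nothing in the pipeline computes time-based physics, so the
tracking cost absorbs the per-frame displacement directly.

Coordinates are 0-based, x = column, y = row, origin top-left.

## Detection and segmentation

Frame and background are converted to luminance (0.299 R + 0.587 G +
0.114 B), Gaussian-smoothed (`segmentation.smoothing_radius`, default σ = 1 px),
and subtracted; the absolute difference is thresholded by Otsu's method plus
a signed bias (`segmentation.otsu_bias`, default 0).

Otsu's criterion always splits the histogram, even when a frame contains no
objects; on such frames the threshold collapses onto the sensor-noise
distribution and the mask fills with small spurious blobs. The binarization
therefore applies an absolute contrast floor (`segmentation.min_threshold`,
default 10 intensity units ≈ 5× the post-smoothing noise level of an 8-bit
sensor with noise SD 2): if the biased Otsu threshold falls below the floor,
the frame is treated as object-free. The floor only participates when Otsu
drops below it, so frames with real objects are unaffected.

Touching islets are split by marker-based watershed. Seeds are pixels whose
Euclidean distance to background exceeds `segmentation.dt_threshold_frac`
(default 0.4) times their own connected component's distance maximum — a
relative threshold, so large and small islets are treated alike — opened
with a disk of `segmentation.opening_radius` (default 2 px) to delete
fragment-sized seeds. The watershed grows each seed over the inverted
distance transform restricted to the mask. For two equal disks whose centers
are 1.5 radii apart, the discrete distance-transform saddle sits at ~0.7–0.8
of the maximum, so deliberate splitting of that configuration needs a seed
threshold around 0.72–0.8 (the default 0.4 is chosen for lightly touching
islets and for robustness of the seed against noise); the suite sweeps this
explicitly.

Per region the measurements are: pixel-count area; centroid; the
marching-squares sub-pixel contour simplified by Douglas–Peucker with 1 px
tolerance — the raw marching-squares polygon overestimates a disk's
perimeter by ~5% (staircase), the simplified polygon is accurate to ~0.3%
on disks and polygons; perimeter = simplified-contour arc length; hull area
= shoelace area of the contour's convex hull (accurate to ~0.3%, vs ~1%
overestimation for the hull pixel count), clamped to ≥ the pixel area so
solidity of convex regions cannot exceed 1; ellipse semiaxes from a direct
least-squares conic fit to the contour (moment-based axes as fallback for
degenerate fits); DTZ⁺ pixel count = region pixels with HSV hue in
`purity.hue_min_deg`–`purity.hue_max_deg` (default 310–360 on the 0–360°
scale); and a border-touch flag. Regions under 5 px cannot support an
ellipse fit and are flagged degenerate; they are ignored by tracking and
metrics.

## Tracking

Between consecutive frames, detection pairs are scored by
J = w_x·|Δx|/min(r₁,r₂) + w_y·|Δy|/min(r₁,r₂) + w_a·|Δa|/min(a₁,a₂) with
r = √(a/π) the equivalent radius (the natural size normalization consistent
with the equivalent-diameter convention) and default weights (1, 0.5, 1):
cross-channel displacement carries half weight because flow is axial. Pairs
with J ≤ `tracking.j_max` (default 2.0 — admits the expected axial
displacement of ~1–1.5 radii per frame while rejecting jumps to neighboring
islets, which cost ≥ 4 under the validation kinematics) are linked greedily
in ascending cost; `tracking.solver: optimal` switches to minimum-total-cost
assignment (Hungarian), which differs only when the greedy order forces a
crossing. Unmatched detections found new tracks; a track unmatched for more
than `tracking.max_missed` (default 2) consecutive frames is retired.

A finalized track needs ≥ `tracking.min_track_length` (default 2) valid
detections, at least one of which does not touch the frame border —
single-frame blobs are likely debris, and border-only tracks are entry/exit
artifacts. The number of finalized tracks is the sample count. Islets that
merge optically for several frames, or re-enter after leaving, are not
re-identified; the generator's validation mode excludes such scenes.

## Metrics

* Equivalent spherical diameter D = 2√(A/π)·δ, frame-averaged per track.
* IEq: diameters binned into the eight standard classes printed as integer
  ranges (50–100, 101–150, …, 351–400, >400 µm). Real-valued diameters use
  round-to-nearest-integer boundaries [50, 100.5), [100.5, 150.5), …,
  [400.5, ∞), so exactly 150 µm falls in the 101–150 class as the IEq
  definition requires; below 50 µm is a fragment contributing 0. Class
  multipliers: 0.167, 0.667, 1.685, 3.499, 6.315, 10.352, 15.833, 22.750.
* Volumes: the fitted ellipse is revolved into an ellipsoid. The "major"
  variant uses the major axis as the third ellipsoid axis, V = (4/3)π·Ma²·Mi;
  the "minor" variant V = (4/3)π·Ma·Mi². Ma and Mi are SEMI-axis lengths:
  this is forced by consistency with the sphere volume (Ma = Mi = 75 µm must
  give (4/3)π·75³ = 1.767 × 10⁶ µm³, the volume of one IEq). Volumes are
  averaged over a track's frames in px³ and converted by δ³. Both variants
  are always computed; `metrics.volume_variant` (default major) selects
  which one populates the headline EFV.
* IEqV = total IEq × 1.767 × 10⁶ µm³.
* Circularity 4πA/P² and solidity A/A_hull, clamped to [0, 1]. Solidity is
  implemented as actual-over-hull (the standard definition, consistent with
  a 0–1 range in which fragmented islets score lower), not hull-over-actual.
* DTZ⁺ ratio: per islet, the frame-averaged fraction of its pixels inside
  the hue window; per sample, both the area-weighted aggregate
  (Σ DTZ⁺ px / Σ islet px) and the unweighted mean of per-islet ratios are
  reported, since the two differ whenever purity correlates with size.
* Scalar per-track metrics are averaged over non-degenerate, non-border
  detections, mirroring the frame-averaging of volume.
* Report statistics use the sample SD (n − 1). Histogram bins default to
  25 µm for diameter and 0.1 for the unit-interval ratios.

## Synthetic validation scenes

The generator renders solid ellipses translating along +x over a flat gray
background (level 210), with per-frame velocity jitter (SD 0.5 px/frame) and
cross-channel jitter (SD 1 px), additive Gaussian sensor noise (SD 2), and a
contiguous stained sector: a fraction of each islet's area rendered at the
stained hue (330°, inside the 310–360° detection window) and the rest at an
unstained yellow-brown hue (55°, outside it). The sector angle is measured
in ellipse-normalized coordinates, which makes the stained *area* fraction
equal the configured fraction exactly (a linear map preserves area ratios of
unit-disk sectors); rendered stained fractions match the configuration to
< 0.02 and rendered areas match π·a·b to < 3%.

Validation scenes use 640 × 360 px frames — a scaled-down field of view
that preserves the geometry (islet diameter ≈ 1/10 of the channel width) —
with 50 islets of equivalent radius 14–26 px (≈ 60–115 µm at the reference
δ), axis ratio 1.0–1.5, velocity 20 px/frame. Islets are laid out in
non-overlapping lanes with surface gaps > 3× the per-frame displacement, so
ground truth attributes every rendered pixel to exactly one islet and the
correct track count is unambiguous. An optional radial boundary perturbation
(`irregularity_amp`) produces non-convex outlines for exercising circularity
and solidity below 1; it is off in validation scenes so the area and stain
oracles stay exact.

What passing these scenes does **not** show: robustness to overlapping or
aggregated islets, lens blur, compression artifacts, illumination drift, or
stain hues near the window boundary. Those failure modes require real
footage and are out of scope for the synthetic validation.

## Numerical choices and degenerate inputs

* Constant foreground → empty mask (no error); empty mask → zero regions.
* Watershed labels are relabeled to contiguous 1..n; determinism is exact
  for identical inputs and configuration (no unseeded randomness anywhere;
  the scene generator is fully determined by its seed).
* Ellipse fits that Qhull/least-squares reject fall back to moment-derived
  axes; contours with < 3 vertices fall back to the pixel-count hull.
* Tracks whose every detection is degenerate or border-touching are excluded
  from metrics and flagged rather than contributing misleading volumes.
* Circularity and solidity are clamped at 1; the raw (unclamped) circularity
  of rasterized convex shapes stays within +0.05 of 1, which the suite
  asserts.

## Known limitations

* Greedy matching is order-dependent in dense crossings; the optimal solver
  is available but the validation scenes are designed not to need it.
* mp4 decoding requires an imageio video plugin at run time; image sequences
  are the portable input path.
* The purity ratio inherits the hue-window rule; stains or illumination that
  move the positive hue outside 310–360° need the window reconfigured.
* 2-D projection: all volumes assume the fitted ellipse reflects the
  mid-plane of an ellipsoid of revolution; true 3-D shape is not recovered.
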