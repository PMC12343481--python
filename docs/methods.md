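# Methods

This note documents the models, parameter choices and numerical
conventions behind `pocketcav`, and what the synthetic-phantom validation
does and does not demonstrate.

## Two-stage cavitation segmentation

The observable is a high-speed video of the water-filled zero-gap pocket
(default calibration: 128×256 px, 20 µm/px, 10 µs frame interval, ~100
frames per laser event), with the laser-onset frame serving as the
background. The primary bubble (PB) stage is, per frame:

1. background subtraction, clipped at zero (the bubble is brighter than
   the background after subtraction; an absolute-difference mode exists
   behind `DetectionParams.subtract_mode="abs"` but is off by default);
2. Gaussian blur, σ = 3 px, reflect padding (reflect avoids the dark
   frame-edge gradient artifacts that constant padding would create);
3. threshold at 75 % of the *per-frame maximum* of the blurred,
   subtracted image. Referencing the frame maximum rather than the
   camera's full scale makes the stage robust to exposure differences,
   and makes an all-zero frame yield an empty mask instead of a full one;
4. morphological opening then closing with a 5 px discrete Euclidean
   disk {(dx,dy): dx²+dy² ≤ r²} (speck removal, then hole filling);
5. convex-hull filling of the largest 8-connected component, which seals
   the gap the dark fiber tip cuts into the top of the bubble;
6. a final opening with a 10 px disk removing larger bright anomalies;
   the PB mask is the largest remaining 8-connected component (ties are
   broken toward the component whose centroid is nearest the fiber
   column).

The secondary-cavitation (SC) stage re-uses the subtracted image with
the PB zeroed out, blurs with σ = 0.7 px, thresholds at 76 % of the
frame maximum, and intersects the result with a horizontal band running
from the fiber-tip row downward by 2.3 mm (mm→px conversion rounds half
away from zero; the band is clipped to the image and it is a
configuration error for it to lie wholly outside). Before zeroing, the
PB mask is dilated by a small disk (`pb_exclusion_dilation_px`, default
5 px): the 75 %-of-max PB contour can sit just inside the bubble's
bright rim, and without the dilation that leftover rim ring — not
cavitation at all — would be classified as SC.

Areas are pixel counts times (pixel size/1000)² in mm². Per-pulse
summaries take the maximum of A_PB(t)/A_SC(t) inside half-open time
windows; reported A_PB/A_SC values are means (± sample SD, n−1
denominator) of those per-pulse maxima, with a warning (not an error)
below the N > 30 pulses the acquisition protocol aggregates. For the
dual-pulse ASW modality the second-pulse window is [t_d, t_d + W) with
W = 200 µs by default, generalizing the fixed example window used when
t_d = 360 µs. Pulses with no detected SC contribute zero to the sweep
averages rather than being excluded; this matches the small means seen
for weakly cavitating conditions, though excluding them would be an
equally defensible convention.

### Structural properties of the pipeline

Two biases follow mathematically from the algorithm and are worth
knowing when interpreting its output:

* **Boundary placement.** For a feature with a flat intensity plateau,
  thresholding the σ-blurred image at fraction f > 0.5 of its maximum
  places the contour Φ⁻¹(f)·σ *inside* the true edge (≈ 2.0 px for
  f = 0.75, σ = 3). The 75 %/76 % operating points were evidently tuned
  on real imagery, where bubbles do not have flat profiles: vapor
  bubbles in transmitted light show a bright rim and a surrounding glow,
  which shifts the threshold contour back onto the physical boundary.
* **Small-object cutoff.** The final opening with a 10 px disk removes
  any object that cannot contain that disk. No object with inscribed
  radius < 10 px (area ≲ 0.13 mm² at 20 µm/px) can survive, whatever the
  earlier stages report. Frames in which the true bubble is smaller than
  this are structurally unmeasurable by this pipeline.

## Cavitation phantom

`make_cavitation_sequence` renders: a static background (linear
illumination gradient 0.25→0.35 plus the dark fiber stripe), a bubble
whose area follows A(t) = A_max sin²(πt/T) — a smooth invented
stand-in that peaks mid-pulse and returns to zero, qualitatively
matching observed growth/collapse — and SC blobs (core radius 1–3 px)
placed uniformly in the band below the fiber tip, active while the
bubble is. Defaults: A_max = 1.8 mm², T = 200 µs, SC density 3 blobs/mm²
in a 1.5 mm band; additive Gaussian noise (σ = 0.01 of dynamic range by
default; validation suites use σ = 0) and one integer seed per call
(identical seed ⇒ bit-identical phantom). Truth masks are the exact
rasterized ellipse/blob footprints; truth areas are mask pixel counts
times the pixel area, with the continuous law value reported separately
as `pb_nominal_area_mm2`.

Appearance is deliberately *not* flat-intensity. Features are rendered
additively as a saturated core plus a dimmer halo skirt (bubble: 5 px
wide at 0.71 of core contrast; blobs: 1.5 px at 0.55), emulating the
bright-rimmed, glowing look of real bubble imagery. The halo parameters
were fixed once by a rasterization calibration study (`scratch/`) run
against the final pipeline, choosing the point where the 75 %/76 %
contours land on the true boundary across the bubble sizes the phantom
produces; with a flat rendering the ~2 px erosion bias above would make
sub-10 % area recovery impossible at any realistic bubble size. The
fiber-tip occlusion follows a simple envelopment model: the bubble stays
below the tip until its semi-minor axis exceeds 20 px, then protrudes
above it by 0.35·(b−20) px, capped at 6 px — small bubbles keep the
vertical extent the 10 px opening requires, while at the peak the
occluded notch is wide and deep enough to genuinely exercise the
convex-hull sealing (a regression test asserts that moving the final
opening before the hull changes the result).

What passing the phantom suite shows: on noise-free phantoms of this
geometry the pipeline recovers per-frame PB masks at Dice ≥ 0.9 and
areas within 10 % wherever the true area is ≥ 0.05 mm², recovers ≥ 80 %
of true SC pixels in the band, and reports nothing above the fiber tip.
What it does not show: performance under real optical phenomena —
shadowgraph-like intensity reversals, refraction through the moving
water meniscus, motion blur, non-Gaussian sensor noise — or for bubble
shapes far from elliptical. The noise model (i.i.d. additive Gaussian)
and illumination model (static linear gradient) are assumptions, not
measurements.

## Bacterial counting

Micrographs (63× brightfield, default 0.103 µm/px) show stained cells as
dark dots on a bright background. The pipeline inverts the image, applies
gamma correction with γ = 2 *on the cells-bright representation* (this
enhances faint cells while compressing the background; applying the same
gamma without inversion would do the opposite), takes Otsu's threshold
over a 256-bin histogram (ties resolved toward the lowest qualifying
threshold), splits touching cells with a marker-controlled watershed on
the negated Euclidean distance transform (markers are distance-transform
maxima ≥ 3 px apart — at the default cell scale this splits pairs whose
centers are 1.4 radii apart while never fragmenting a single round
cell), and counts particles with area in [0, 300) µm², half-open, in
ImageJ "Analyze Particles" semantics where the size range is an area
range. Each particle is assigned to one of four quadrants (2×2
floor-split tiling; odd dimensions leave the extra row/column with the
lower/right tiles) by its centroid, and a remaining-fraction is computed
against a control image as 100 · total/total_control, with per-quadrant
fractions and their mean ± SD.

Limitations: Otsu's criterion degrades when the foreground occupies
≪ 1 % of the image — with only ~10 cells the field of view must be
cropped accordingly (the validation suite uses a 256² patch for n = 10
and 512² for n ≥ 100). The phantom places round, equal-sized,
Gaussian-profile cells; rod-shaped, variably stained or multi-layered
(biofilm) morphologies are outside what the recovery tests demonstrate.

## Velocimetry

Particles are detected as connected regions above an absolute intensity
threshold (default 0.5) with sub-pixel intensity-weighted centroids, and
matched between consecutive frames by mutual nearest neighbours within a
search radius (default 10 px); unmatched detections are dropped and
counted. Speed is |d| · pixel_size/frame_interval (µm/µs ≡ m/s), so
5 px/frame at 20 µm/px and 10 µs is 10 m/s. Mutual-NN matching replaces
the manual frame-by-frame visual tracking it automates; it is
unambiguous when inter-particle spacing exceeds twice the frame-to-frame
displacement, which the phantom enforces by a 12 px minimum separation.
The summary velocity is the maximum over matches (with the mean also
reported), treating the flow-speed figure as a peak value.

## Physics utilities

Fluence: E/(π r²) with r the fiber radius — 10 mJ through a 400 µm fiber
is 7.96 J/cm² (displayed rounded to 8), 30 mJ is 23.87 (≈ 24). Young's
modulus from storage modulus: E = 3 G′, the incompressible-elastomer
approximation, mapping the soft-plate range G′ = 14–29 kPa to
E = 42–87 kPa. ASW pairs deliver twice the per-pulse energy; the delay
grid is the inclusive sequence 200, 210, …, 650 µs (46 points).

## Numerical conventions

* Intensities are normalized to [0, 1] on load regardless of 8/16-bit
  source; phantom output is written as 8-bit TIFF.
* Morphology treats pixels outside the image as background, i.e. the
  exact set-arithmetic definitions on the finite grid (scipy.ndimage
  with `border_value=0`); an object touching the border erodes from the
  border side too.
* The convex hull is rasterized by pixel-center inclusion in the hull of
  the foreground pixel centers, which makes `convex_hull_fill` exactly
  idempotent; degenerate (collinear) components pass through unchanged.
* 8-connectivity is used for components everywhere.
* Validation problem sizes: 30-frame sequences, 8–20 phantom seeds,
  counting fields up to 512², 10–30 sweep replicates of 46 delays × 16
  pulses — sizes at which every recovery metric is stable to the third
  decimal across seeds.
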