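# Methods

`dermoborder` quantifies border irregularity of a pigmented skin lesion in a
dermoscopic color image.  The output feeding the clinical score is the list
of border irregularities (turning points of the borderline function) and the
B component of the ABCD rule derived from them.  This note records the
model, the numerical choices, and what the synthetic validation does and
does not show.

## Pipeline

1. **Black frame removal.**  Digitization can leave a black frame around the
   image.  A pixel is *black* when its HSL lightness L = (max(R,G,B) +
   min(R,G,B))/2 is below 15 (on 0–255).  Scanning inward from each side,
   consecutive rows/columns with ≥ 50% black pixels form the frame band; the
   band plus 10 extra rows (the light inner rim) is cropped.  The scan stops
   at the first non-qualifying line, so interior dark rows are never
   removed, and the crop offsets are kept for coordinate mapping.

2. **Hair removal.**  On the NTSC-1953 grayscale image (0.299 R + 0.587 G +
   0.114 B), a black top-hat transform — morphological closing with a disc
   (default radius 5 px) minus the image — responds to dark structures
   thinner than the disc.  The response is binarized (default absolute
   threshold 20; Otsu optional) and connected components are kept as hairs
   only if elongated (major/minor axis ≥ 4) and long (major axis ≥ 30 px),
   which excludes dots and globules.  Hair pixels are replaced by the
   per-channel mean of non-hair pixels within a 5 px disc, iterating from
   the mask boundary inward so arbitrarily thick hairs are covered.
   Component perimeters are logged but carry no criterion (no principled
   threshold presented itself that axis measurements do not already cover).

3. **Segmentation.**  The lesion lies inside the image, so the healthy skin
   is one region touching the upper-left corner.  Seeded region growing
   starts there: the 4-connected frontier pixel with the smallest
   δ = |intensity − region mean| is admitted while δ ≤ tolerance, the mean
   updating after every admission (best-first growth with a lazy-priority
   heap; ties broken in row-major order, so masks are bit-reproducible).
   The default tolerance is 0.1 × the image's intensity range, which adapts
   across exposure levels.  The lesion is the complement's largest
   4-connected component with interior holes filled.  If the corner pixel is
   a noise outlier the initial mean can misrepresent the skin and growth
   stalls within a few pixels; the pipeline detects this (healthy region
   < 25% of the image) and retries from deterministic fallback seeds along
   the border.

4. **Alignment.**  The rotation that makes the lesion's principal axis
   horizontal is θ = ½·atan2(2 μ₁₁, μ₂₀ − μ₀₂) from the mask's central
   second moments (x = columns).  Rotation is about the lesion centroid onto
   an enlarged canvas (no clipping); continuous rasters use bilinear
   interpolation, binary masks nearest-neighbour.  A circular mask (equal
   moments within 1e−6) rotates by 0.  The affine record is serialized so
   every detection maps back to raw-image coordinates within 0.5 px.

5. **Borderline function.**  The boundary of the rotated mask is traced
   (Moore neighbourhood, clockwise, starting at the topmost-then-leftmost
   pixel) and cut into four segments at the boundary points nearest the rays
   from the centroid to the bounding-box vertices; when such a ray crosses
   the boundary several times, the outermost crossing is the split point.
   Each segment is converted to a height profile *parameterized by the
   boundary walk itself*: one sample per trace pixel, whose value is the
   pixel's distance from the canvas edge the segment faces.  Signs are
   chosen so an outward protrusion is a local **maximum** on every side
   (top: (H−1)−row, right: col, bottom: row, left: (W−1)−col); the absolute
   offsets are immaterial because assembly subtracts them.  Arc-order
   parameterization was chosen over a per-column/per-row sweep because the
   latter collapses boundary detail wherever the contour overhangs itself in
   the sweep direction — near the ±45° corner regions this merges adjacent
   irregularities across segment junctions (at 24 bumps per revolution,
   three pairs can fuse), an effect that is angular and therefore
   scale-invariant.  The count of sweep positions a segment visits more than
   twice is still reported as the `overhang_positions` diagnostic.

   The four profiles are concatenated clockwise (top, right, bottom, left);
   at each junction the incoming segment is shifted by the value gap so the
   assembled signal is exactly continuous there.  The shift is cumulative
   left-to-right; the residual closure gap between the last and first sample
   is recorded but not corrected — the borderline is an open curve.

6. **Smoothing and detection.**  The signal is convolved with a sampled,
   renormalized Gaussian kernel (size 15, σ = 2.5, edge-replicated
   boundaries).  The size-15 window is the method's fixed default; σ is
   chosen with the standard size ≈ 6σ coupling, since a window that wide
   needs a comparable width to be meaningful.  Irregularities are
   turning points: indices where the first difference changes sign from +
   to −; zero-difference plateaus bounded by a rise and a fall yield one
   call at the floor midpoint; endpoints are never called.

   Two refinements handle the construction's own artifacts:

   * **Junction de-duplication.**  A protrusion whose apex coincides with a
     split point is measured by both adjacent sweeps and appears as one peak
     on each side of the junction with a shallow saddle exactly at it.  Two
     consecutive maxima straddling a junction within the smoothing-kernel
     support are therefore merged (higher peak kept); the same rule joins
     the first and last calls across the open ends, which meet at the fourth
     split point.  Set `merge_window=None` for the uncorrected behaviour.
   * **Prominence floor.**  Rasterization leaves sub-pixel ripples that
     survive smoothing; calls with topographic prominence below 0.5 px (the
     sub-pixel boundary) are dropped.  Set `min_prominence=0` for strict
     sign-change detection.

7. **Scores.**  The border score B is the number of the signal's eight
   equal octants containing at least one irregularity (0–8).  With manually
   assessed asymmetry A ∈ {0..2}, colors C ∈ {1..6} and differential
   structures D ∈ {1..5}, the total dermoscopy score is
   TDS = 1.3·A + 0.1·B + 0.5·C + 0.5·D, classified benign below 4.75,
   highly suspicious above 5.45, suspicious between (the integer score grid
   steps in 0.1, so the nominal [4.75, 4.8) gap is unreachable; a
   non-integer TDS falling there is treated as suspicious, conservative
   toward follow-up).

## Radial baseline and evaluation

The comparison method is the classical centroid (radial) distance curve:
distance from the lesion centroid to the boundary per angle, taking the
outermost crossing when a ray crosses several times (the per-angle crossing
count is reported, since multiple crossings are exactly where this signature
loses information).  It is smoothed with the same Gaussian kernel
(circularly) and peaks are detected with the same turning-point rule.

Detections are matched to ground-truth positions one-to-one, greedily by
increasing circular arc distance along the boundary, with tolerance 2% of
the boundary length; matched pairs are TP, leftover detections FP, leftover
truths FN.  Sensitivity = TP/(TP+FN), precision = TP/(TP+FP).  True
negatives are undefined for boundary irregularities, so no accuracy is
reported.

## Phantom generator

Phantoms emulate what the pipeline manipulates, not photorealism: a dark
quasi-elliptical lesion (intensity 70) on homogeneous skin (200) with
additive Gaussian noise, optional dark hair strokes (Bézier curves, 1–3 px
wide), and an optional black frame.  The contour is polar:
r(t) = ellipse(a=72, b=52) + A·((1+cos k(t−φ))/2)^s with a seeded random
phase, so the bump train has exactly k maxima at known angles (verified at
construction; invalid combinations raise rather than emit wrong truth).
Default amplitude A = 12 px, sharpness s = 1 (pure cosine — flat-valley
shapes re-expose the ellipse arch between bumps), noise σ = 8 with contrast
130 (> 4σ), canvas 280².  Tiers: `clean` (no noise/hair/frame), `standard`
(noise + frame), `hard` (noise + 3 hairs + frame + 30° orientation).

Lobed phantoms probe the multi-crossing geometry: overhanging shelf arcs
(14 px thick — too wide for the top-hat, so the hair filter cannot inpaint
them) attached by a neck and ramping outward so the tip is the lobe's
extremal point, with one bump tucked radially under each shelf's open end.
Centroid rays through a shelf cross the boundary three times; the hidden
bump is invisible to the radial signature (the outermost crossing is the
shelf) but protrudes past the shelf's row/column extent, so the
edge-distance profiles still see it.  Lobe pairs sit on perpendicular
diagonals so their second moments roughly cancel and alignment stays near
the body axes; visible bumps sit near the axis directions (mid-segment).

What passing on phantoms does **not** show: robustness to variegated lesion
coloring, low contrast, pigment networks, air bubbles, ruler markings, or
vignetting — real dermoscopic conditions the generator deliberately omits.

## Known limitations

* **Corner attenuation.**  Near the ±45° corner regions the profile ramp
  slope approaches 1 sample/sample, and a bump produces a detectable
  reversal only if its flank slope exceeds the ramp — roughly A·k/(2r) > 1
  for amplitude A, bump count k, lesion radius r.  Below that, corner bumps
  yield maxima of prominence comparable to the rasterization noise floor:
  at k = 4 they can disappear entirely while the segment's own elliptical
  arch apex emerges instead, and their detection is not stable under
  re-rasterization (rotation).  The phantom's two-fold symmetry doubles
  every such marginal error.  This is intrinsic to measuring distance along
  fixed canvas axes.
* A smooth lesion still yields four arch maxima (one per segment) — the
  method's floor is ~4 "irregularities" for a circle, which the B score
  tolerates (4 octants at most).
* The construction presumes the centroid lies inside the lesion; strongly
  concave lesions violating this are rejected with a diagnostic rather than
  mis-scored.
* Single-peak prominence cannot distinguish a shallow genuine bump from a
  strong arch ripple; the 0.5 px floor is a compromise, and both
  populations exist near it.

## Reproducibility

Every phantom is a pure function of its spec and seed; the region grower,
tracer and detector are deterministic with fixed tie-breaks; pipeline
results serialize to byte-identical JSON across runs.  The validation
experiment sizes (1,000 random signals, 50/100/20/20 phantoms, 810 TDS
combinations) are the package's standing acceptance suite
(`tests/test_acceptance.py`, `scripts/acceptance.py`).
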