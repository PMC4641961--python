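# dermoborder

Automatic assessment of **border irregularity** in dermoscopic color images.

Border irregularity — ragged, notched edges with abrupt pigment cut-offs —
is one of the strongest dermoscopic predictors of melanoma and the B
component of the ABCD rule, in which the total dermoscopy score

&nbsp;&nbsp;&nbsp;&nbsp;TDS = 1.3·A + 0.1·B + 0.5·C + 0.5·D

classifies a melanocytic lesion as benign (TDS < 4.75), suspicious, or
highly suspicious (TDS > 5.45).  Clinician estimates of B are subjective
and not invariant to image rotation; `dermoborder` computes it
automatically.

## Method

Given an RGB dermoscopic image, the pipeline:

1. removes the black digitization frame (HSL-lightness rule) and removes /
   inpaints dark thick hairs (black top-hat transform on the NTSC grayscale,
   elongation-filtered, neighbourhood-mean inpainting);
2. segments the lesion by seeded region growing of the healthy skin from
   the image corner (best-first, running region mean, admission while
   δ = |intensity − mean| ≤ tolerance) and taking the cleaned complement;
3. rotates the lesion so its principal axis (from central second moments)
   is horizontal, with bilinear interpolation on an enlarged canvas;
4. builds the **borderline function**: the boundary is traced clockwise,
   split into four segments at the boundary points nearest the rays from
   the centroid to the bounding-box vertices, each segment becomes a
   distance-to-canvas-edge profile, and the four profiles are concatenated
   with the junction gaps subtracted — a single 1-D curve in which every
   outward protrusion of the border is a local maximum;
5. smooths the curve with a size-15 Gaussian and detects irregularities as
   **turning points** — indices where the derivative changes sign from + to
   − — then reports the count, each call's position in the original image,
   and the border score B (number of the curve's eight octants containing a
   call).

A radial (centroid) distance curve baseline and a sensitivity/precision
evaluator with greedy arc-length matching are included for comparison
studies, along with a phantom generator that renders lesions with exactly
known ground truth (bump count and positions, hair strokes, frame) so the
whole pipeline is testable without clinical data.

See `docs/methods.md` for the model details, parameter defaults and known
limitations.

## Worked example

Generate a standard-tier phantom (noise + frame) with 12 boundary bumps,
run the pipeline, and score it against the known truth:

```sh
$ dermoborder synth --tier standard --seed 7 --k 12 --out phantom
phantom written to phantom (k=12)

$ dermoborder run phantom/image.png -o result --abcd 1 3 2
irregularities: 12  B score: 8

$ dermoborder evaluate --result result/result.json --truth-dir phantom --out report.csv
aggregate[all],1,12,0,0,1.0000,1.0000
```

The pipeline found all 12 constructed bumps (sensitivity and precision
1.0000 in the report's aggregate row) and scored B = 8: every octant of the
borderline contains an irregularity.  With the manually supplied A = 1,
C = 3, D = 2 the result record contains

```json
"abcd": {"A": 1, "B": 8, "C": 3, "D": 2, "tds": 4.6, "classification": "benign"}
```

— a TDS of 1.3 + 0.8 + 1.5 + 1.0 = 4.6, below the 4.75 threshold.  Each
detected call carries its index on the borderline, its (row, col) position
mapped back to the raw input image, its prominence in pixels, and the
boundary segment it lies on, e.g.

```json
{"coord": [87.98, 94.02], "index": 13, "prominence": 3.26, "segment": "top"}
```

Subcommands `preprocess`, `segment`, `borderline` and `detect` expose the
individual stages; every tunable lives in one TOML config
(`dermoborder run --config my.toml ...`, CLI flags take precedence).

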