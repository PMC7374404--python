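# Methods

## Model and assumptions

The localiser treats pupil detection as one-dimensional template
matching, twice. It assumes (i) the eye frame is a tight crop around a
single open eye, (ii) the iris is approximately circular and darker
than the surrounding sclera, with the pupil its darkest part, and
(iii) the iris spans a roughly fixed fraction of the eye-frame width,
so a template 0.4 frame-widths wide brackets the iris diameter across
subjects and resolutions. It makes no use of colour, gradients or
learned appearance; everything runs on the greyscale intensity pattern.

Two facts make the cascade one-dimensional. The horizontal template is
resized to the full frame height, so it can only slide in x: one score
per column offset. The vertical template is as wide as the iris
rectangle, so it can only slide in y. Each pass is a plain
normalized-correlation scan at one-pixel stride.

## Score, threshold, aggregation

The matching score is the normalized correlation coefficient of the
mean-centred template and patch, hence invariant to any positive affine
transform of patch intensities (illumination scale and offset). A
configuration switch (`centred=False`) provides the un-centred
normalized product instead; the mean-centred form is the default
because it is the textbook correlation coefficient and carries the
affine invariance.

A pass's candidate set is every stride position whose score is
*strictly* greater than the 90th percentile (linear interpolation
between order statistics) of that pass's scores. If no score is
strictly greater — an all-tie degenerate frame — the candidate set
falls back to the argmax positions so it is never empty. The reported
position is the arithmetic mean of the candidate coordinates, rounded
half-to-even. Averaging the top decile rather than taking the argmax
trades a small amount of peak sharpness for robustness to local maxima,
which dominate failure cases at these resolutions.

Degenerate (zero-variance) patches score 0 rather than raising, so flat
sclera or saturated regions never abort a scan; a fully constant frame
raises a localisation error with a machine-readable reason.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `width_fraction` | 0.4 | horizontal template width as a fraction of eye-frame width |
| `height_fraction` | 0.4 | vertical template height as a fraction of iris-rectangle height |
| `quantile` | 90 | percentile of the score distribution above which positions become candidates |
| `centred` | true | mean-centre template and patch before correlating |
| `pad` | true | white rim of half the template extent before each pass |
| crop `margin` | 0 | eye frames are the exact landmark bounding box |

The padding rim is the smallest (half the template extent per side)
that lets the template centre reach the frame edges, which is what
extreme-gaze matching requires. Adapted template dimensions round
half-up and clamp to ≥ 1 pixel; the centre formula C = R + k/2 uses
integer floor. Template resampling is bilinear, with a low-pass
prefilter when shrinking so strong downscales keep the template's
structure instead of point-sampling its interior.

### Numerical conventions

Coordinates are 0-based, x = column, y = row, pixel-centre addressing,
stated once and used everywhere; 1-based annotation dialects are
converted at the file boundary. Candidate means round half-to-even
(bias-free ties); kernel dimensions round half-up. When the iris
rectangle is clipped by a frame edge and is narrower than the template,
the template is cropped to the columns that were aligned with the
rectangle at stride R_x — not resized — so the disc keeps its position
relative to the visible iris.

## Custom kernels

When example iris patches are supplied, the template is their
pixel-wise mean after resizing every patch to the element-wise median
patch dimensions, rounded half-up to integer intensities. The mean is
the simplest estimator that generalises across iris colour and texture;
no clustering or selection is attempted. Without patches the analytic
fallback is a dark disc (intensity 20, diameter 0.9 of the shorter
side) on a light field (intensity 235).

## Synthetic data

The renderer emulates the regime the method targets: a dark iris disc
with a concentric darker pupil on a lighter sclera field, optionally a
top eyelid band, a horizontal illumination gradient, and additive
Gaussian sensor noise clipped to [0, 255] (applied last, mimicking
saturation). Discs are rasterised by centre-of-pixel inclusion. The
eyelid band intensity is sclera − 25, a skin-like tone distinct from
both iris and pupil so full occlusion leaves neither visible.

The default sampling distribution: frame width uniform 24–80 px at a
2.5:1 aspect ratio, iris radius uniform 0.12–0.22 × frame width
(clamped so the iris fits the frame height), pupil radius 0.4 × iris
radius, gaze position uniform over the span where the iris stays
visible, sclera 170–230, iris 60–110, pupil 30–50 below the iris,
gradient amplitude 0–20, noise σ 0–10. The two-eye face mock-up places
two such 50 × 20 px eyes with an inner-corner gap of one eye width, the
anthropometric convention underlying the interocular-normalized
metrics, giving an interocular distance of about twice the eye width.

What the synthetic data does **not** emulate: iris texture, specular
corneal reflections, eyelashes and eyebrows, skin texture, perspective
and head pose, motion blur, and compression artefacts. Passing the
synthetic benchmarks therefore demonstrates the geometric and numerical
correctness of the cascade under controlled nuisance factors, not
performance on photographs; the annotation readers exist so users can
run the published face benchmarks themselves.

## Evaluation conventions

wec/bec are computed per frame; per-axis MAE and R² pool both eyes
(this pooling is recorded in the report metadata). Threshold
comparisons are inclusive (error ≤ t). S_ED uses the geometry of the
same eye-frame crop the estimate came from. The evaluation join fails
closed on any identifier mismatch between detections and annotations.

## Problem sizes

The bundled experiments use 200 eye frames for parameter recovery, 100
two-eye mock-ups for the interocular metrics, and 100 noiseless renders
for the edge-gaze sweep — sizes at which every statistic reported is
stable to within a percentage point or two across seeds while the whole
suite runs in seconds.

## Known limitations

- **Clipped irises.** When the disc centre is closer to a left/right
  frame edge than about half its radius, part of the iris does not
  exist in the image and the correlation peak itself shifts inward: at
  positions overhanging the frame the template's dark disc lies over
  the white rim, which is brighter than any sclera, so the score always
  improves by sliding inward until the whole template disc covers
  visible pixels. Recovery degrades smoothly with clipping depth
  (see `examples/03_extreme_gaze.py`); edge-flush but fully visible
  irises are recovered to pixel accuracy.
- **Even template sizes** carry an inherent +0.5 px bias from the
  C = R + k/2 centre formula, visible as occasional one-pixel offsets.
- Closed or near-closed eyes are not detected; a fully occluded frame
  simply produces a low-confidence (often wrong) estimate. Callers can
  screen frames by contrast before localisation.
- One estimate per frame; no sub-pixel refinement, ellipse fitting or
  temporal smoothing.
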