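# Methods

## Sensor model and preprocessing

A drawing session is a sequence of samples at a nominal 50 Hz (20 ms period):
time in seconds, pen position in canvas pixels (origin top-left, y down;
default canvas 1600×1320 px at 0.004 cm/px, both configurable), and a touch
event per sample: −1 pen-down onset, 0 move while touching, 1 pen-up.
Consecutive samples sharing a timestamp are merged (the last wins) before
speeds are computed, so the speed `v[n] = |Δposition| / Δt` is always
defined; `v[0] = 0` by convention.

The two figures are separated at the longest run of pen-up events strictly
inside the trace; ties go to the earliest run. `nf1` is the sample before
that run, `nf2` the first sample after it. A trace without an interior
pen-up run is rejected as a single-figure drawing. The interlock endpoints
are the left-positioned figure's rightmost sample and the right-positioned
figure's leftmost sample (first index on ties); which drawn figure is "left"
is decided by comparing mean x, so right-first drawers are handled
symmetrically.

### Isolated speed spikes

A sample whose speed exceeds the zero tolerance and is more than 8× both of
its neighbours is treated as a positional discontinuity rather than motion —
a pen cannot physically produce a one-sample 0→fast→0 excursion at 50 Hz.
Such samples (typically the restart jump across an undrawn contour gap) are
clamped to zero speed for both peak counting and rest-point clustering; the
pen is at rest on both sides of the jump.

## Feature extraction

**Velocity peaks.** Drawing kinematics: along each straight edge the pen
accelerates and then decelerates to (near) zero at the corner, so the number
of velocity peaks equals the number of edges. The speed series of one
figure is cleaned of isolated spikes, smoothed with a 5-sample moving
average (edge-padded so constant series gain no boundary artifacts), and
local maxima at ≥ 20 % of the segment maximum are counted; maxima not
separated by a near-zero trough merge into one peak. The trough tolerance is
`max(1 px per sample period, 5 % of the segment's top smoothed speed)`: the
absolute floor covers true rest, the relative term covers corners where
sensor jitter keeps raw samples marginally above the floor. A constant-speed
segment has no interior local maxima and yields zero peaks.

**Angle count.** A figure whose drawn pixels match the pentagon
segmentation mask at `pf ≥ pth1 = 75 %` counts 5 angles outright; otherwise
the velocity peak count is used. All threshold comparisons in this package
are inclusive (≥), matching the score-assignment table.

**Interlock distance and aspect ratio.** `dL` is the Euclidean distance in
cm between the two interlock endpoint samples, negative when the left
figure's rightmost point lies right of the right figure's leftmost point
(overlap). `|Δx/Δy|` is the endpoints' coordinate-difference ratio; a
rhombus-shaped interlock has a wide, flat tip pair, so the ratio is large.
`Δy = 0` returns an infinite sentinel that compares ≥ any finite threshold
(`Δx = 0` too returns 0). The denominator is `y[n1] − y[n2]`.

**Openings.** Zero-velocity samples (speed < 1 px per sample period, pen
touching) concentrate at corners. They are clustered with k-means
(scikit-learn, `n_init=10`, seeded; k = the figure's angle count; k is
reduced and the figure flagged degenerate if fewer distinct points exist).
Each cluster's dispersion is the mean member-to-centre distance in cm. A
closed corner is a dwell blob a few pixels wide; a contour gap leaves two
rest blobs (stroke end, stroke restart) that merge into one cluster whose
dispersion exceeds `δth = 0.1 cm` (the threshold sits above the 20 px
≈ 0.08 cm line width). The opening flag is 1 iff any dispersion exceeds
`δth`.

**Tremor.** The count of adjacent event pairs (1, −1) — a pen-up
immediately followed by a pen-down — per figure; the tremor flag is 1 iff
the count reaches `eth = 5`. The published flag algebra is internally
inconsistent with the score table's plain meaning ("no tremor → 1 point");
this package exposes *tremor present* flags and awards the point when both
are 0. The closure flags are handled the same way (*opening present*).

## Segmentation

The drawing is inked with 20 px round-capped strokes on the full canvas
wherever the pen was touching (a step is drawn unless the previous sample
was pen-up), then area-downsampled to 128×128 and binarized at 0.15. The
three match percentages are `p = 100·|mask ∩ drawn| / |drawn|` with the
drawn reference being the figure's own pixels (`n ≤ nf1`, `n ≥ nf2`) or the
interlock sub-trace (`n1..n2`). An empty reference raises; the pipeline
converts that to `p = 0` with a warning (e.g. `pL` when no interlock ink
exists).

**U-Net.** Both segmentation models use the same architecture: 4
contracting levels of two 3×3 same-padded convolutions + ReLU and 2×2
max-pooling, feature channels doubling from 16 to 256 at the bottleneck, 4
expanding levels of learnable 2×2 up-convolution, skip concatenation and two
3×3 convolutions, and a final 1×1 convolution onto one logit map — 23
convolutional layers in total. It is implemented directly in NumPy (im2col
GEMM convolutions, argmax-routed pooling, Adam, positively-weighted binary
cross-entropy with logits, float32, fully seeded), sized for CPU training on
synthetic data. Defaults: batch 4, learning rate 1.5e-3 (1e-3 in the config
default), positive-class weight 4 to counter the ~90 % background fraction,
mask binarization of the sigmoid output at 0.5. At desk scale (96 training
images, 8 epochs, one CPU) it reaches ≈ 0.97 held-out pixel accuracy and
≈ 0.74 mean IoU against the oracle masks.

**Oracle segmenter.** For synthetic data with known geometry, the pentagon
mask of a truly five-vertex figure is its contour band (line width, dilated
2 px at 128×128 to absorb resampling error; empty for non-pentagons) and the
interlock mask is the filled true overlap polygon dilated 3 px. The
interlock dilation matters: the drawn tip strokes straddle the overlap
region's boundary, so an undilated fill would cap `pL` near 50 % even for a
perfect drawing. Per-figure assignment of the learned pentagon prediction
uses pixels near each figure's own samples (the sample-index split mapped
through rasterization), mirroring how the index split accompanies the
learned model.

## Score assignment

Angles: 4 if both `pf ≥ 75 %`; else by `NA1+NA2`: {9, 11} → 3, {8, 12} → 2,
5–7 → 1, otherwise (< 5 or > 12, including the sum 13 left unmapped by the
published table) → 0. Distance/intersection, rules tested most-specific
first: 4 if `pL ≥ 75 % ∧ dL < −ε ∧ ratio ≥ 1.12`; else 3 if `dL < −ε`
(interlocked; the published worked examples score high-`pL` non-rhombus
interlocks as 3, so no low-`pL` clause is applied, and an interlock whose
rhombus shape is not confirmed by segmentation also falls here); else 2 if
`|dL| ≤ ε = 0.01 cm` (touching); else 1 if `dL < 1 cm`; else 0. Closure:
`2 − openings`. Tremor: 1 iff neither figure shows tremor. Total = sum,
0–11. When a subject draws more than one copy, the last complete pair of
figures is the one scored (the figure split keys on the longest pause, which
precedes the final copy).

## Synthetic data generator

The generator emulates exactly the phenomena the scorer measures, with
ground truth attached. Geometry: two regular polygons (3–6+ vertices,
default circumradius 1.52 cm, auto-shrunk to fit the canvas) with facing
tips. Interlock modes: *rhombus* (tips overlap 0.9 cm in x, 0.15 cm in y →
ratio ≈ 6), *non_rhombus* (overlap 0.6 cm with a vertical tip offset chosen
from the figures' corner wedge angles so the tips sit inside the opposite
figure while the ratio stays below 1.12; infeasible for triangles),
*touching* (tip gap ≈ 1 px after closure overshoots), *gap* (configurable
separation in cm). The true interlock polygon is the shapely intersection
of the two figures.

Kinematics: per-edge triangular speed profile (≈ 22 samples per
reference-edge length), ≥ 3 zero-displacement dwell samples at each corner,
Gaussian pen jitter of 0.3 px per coordinate. The first figure starts and
ends at its interlock tip with a 2 px outward closure overshoot; the second
starts with a 2 px outward pre-stroke into its tip. This pins the
arg-extremal x samples to the tips and confines the interlock sub-trace to
the overlap region — without it, the interlock match percentage of even a
perfect drawing would be far below the published ≈ 100 % regime, because the
sub-trace between the endpoints would sweep most of a figure.

Openings remove a 0.25 cm arc on each side of one corner (capped at 30 % of
the edge), so the corner's rest cluster splits into two blobs ~0.3–0.4 cm
apart whose merged dispersion (≈ 0.13–0.2 cm) exceeds `δth`, while all ink
stays on the true contour (match percentages unaffected). Tremor injection
replaces isolated mid-edge 0-events with (1, −1) pairs, spaced ≥ 3 samples
apart — exactly the detection primitive, recoverable with zero error.

The documented dataset distribution draws vertex counts {5: 0.6, 4: 0.3,
6: 0.1} per figure, interlock modes {rhombus 0.4, non_rhombus 0.2, touching
0.2, gap 0.2} (gap lengths split below/above the 1 cm score boundary),
openings at 0.2 per figure, tremor counts ≥ 5 at 0.2 per figure (else 0–2),
and right-first drawing order at 0.1.

**What the generator does not emulate** — and hence what passing tests do
not show about clinical data: curved or retraced strokes, hesitation pauses
inside edges, variable drawing speed between subjects, micrographia,
closing-in behaviour, multiple discarded copies, and realistic pathological
tremor waveforms (only the pen lift/touch signature is modelled). Agreement
rates on synthetic data are an upper bound on clinical performance.

## Evaluation

Predicted and true sub-scores are binarized per parameter (default: the
parameter's maximum sub-score is the positive class, configurable
one-vs-rest at any level) and tallied into TP/FP/FN/TN; sensitivity
TP/(TP+FN), specificity TN/(TN+FP), accuracy and precision are reported as
percentages rounded half-up to two decimals (half-up is required to
reproduce published-style tables, e.g. 87/96 → 90.63). Zero denominators
are flagged as undefined rather than propagated as NaN.

## Numerical and design choices

- All rule thresholds are inclusive; the assignment table governs where
  prose and formulas disagree about strict vs inclusive comparisons.
- Zero-velocity tolerance 1 px per sample period: exact zeros are rare
  under touch jitter.
- k-means initialization is seeded with 10 restarts; assignments are
  deterministic given the seed.
- Degenerate inputs: empty overlap references score 0 % with a warning;
  fewer distinct rest points than clusters reduce k and flag the figure;
  traces without an interior pen-up run are rejected with a diagnostic.
- Desk-scale study sizes: 200 synthetic drawings for end-to-end recovery,
  128 images (96 train / 32 held out, 8 epochs) for segmentation training —
  chosen to keep a full verification run on one CPU core in minutes while
  leaving clear margins over the acceptance thresholds.
- Whole-pipeline scoring of one trace takes well under a second on one CPU
  core, in the same order as the published execution-time regime.

## Known limitations

- The learned models are trained on synthetic drawings only; no claim is
  made that they transfer to real handwriting without retraining.
- Figures drawn with interleaved strokes (returning to the first figure
  after starting the second) violate the longest-pause split assumption.
- The k = NA clustering inherits errors in the angle count: a badly wrong
  peak count distorts the opening test (flagged via the degenerate list).
- `|Δx/Δy|` is undefined for a perfectly vertical tip pair; the infinite
  sentinel deliberately classifies that geometry as rhombus-compatible.
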