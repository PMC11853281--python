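# Methods

`neomotion` turns a depth-camera video stream of a neonate into a
per-second binary activity signal ("motion" / "no motion").  This note
describes the processing model, its assumptions, the parameters that
matter, what the synthetic scene generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Signal model

A depth camera delivers a raster of distances (mm) to the nearest surface
at ~30 fps.  Neonatal activity — limb motion, head turns, gross torso
movement — appears as depth changes of roughly 5–150 mm over tens to
hundreds of pixels between frames one second apart.  Two nuisance
processes share the raster: quiet breathing (≈ 1–3 mm chest-surface
modulation, *not* counted as activity) and sensor noise (per-pixel jitter
growing with distance, no-return dropouts encoded as 0, sparse far
outliers).

### Temporal averaging and denoising cascade

The stream is divided into 1 s spans.  At each span boundary a median
frame is computed from the 10 frames starting at the boundary; the median
is robust to single-frame speckle, and a pixel invalid in more than half
of its contributing frames stays invalid.  A clip with *n* spans yields
*n* averaged frames and *n − 1* difference frames; the difference (and
feature vector, and truth label) for second *t* covers the closed
interval [*t*, *t*+1].

Each averaged frame is then percentile-clipped: depths above the 87th or
below the 3rd percentile of the in-range (200–1000 mm) depths are
invalidated.  The point of this stage is scene segmentation on the cheap —
the band between the percentiles is where the neonate lies; nearer
structure (isolette walls, nesting rolls) and farther structure (cot
surface, mattress) are stripped.  Consecutive clipped frames are
subtracted where both are valid; 5×5 then 3×3 *masked* median filters
smooth the difference raster (invalid pixels are excluded from the window
median rather than zero-filled, which would drag medians toward zero at
mask borders); differences with |Δ| > 150 mm are discarded as too large to
be neonatal motion (both signs — motion toward and away from the camera);
and connected regions of active (valid, nonzero) pixels smaller than 40 px
are discarded as too small to be genuine motion (8-connectivity by
default).

Key parameters (all in `DenoiseConfig`): `frames_per_median` 10,
percentiles 3/87 over 200–1000 mm, kernels (5, 3), `max_diff_mm` 150,
`min_region_px` 40.  These are the published operating point of the
pipeline; the percentiles in particular were reported as the outcome of a
grid search on the clinical data.

### Features

Sixteen per-second features summarize each difference frame together with
the clipped averaged depth frame at the interval start.  The published
description fixes the four groups and their intent but not closed
formulas; the definitions below are this package's interpretation, with
all constants in `FeatureConfig`:

* **Spatial scale (5)** — fraction of valid pixels with |Δ| above 1, 3, 6,
  12, 25 mm, multiplied by (mean valid depth / 500 mm)².  The inverse
  projection law means a patch of fixed physical size covers ~1/d² pixels,
  so the quadratic factor makes the same physical motion score the same
  near and far.
* **Summed difference (4)** — Σ|Δ| over pixels with |Δ| above 1, 5, 15,
  40 mm, per valid pixel: motion magnitude, sensitive to strong motion
  over small areas.
* **Average depth (4)** — mean, median, 25th, 75th percentile of valid
  depths: distance context that lets the forest condition the difference
  features on range.
* **Skew set (3)** — standard deviation of depths at or below their 75th
  percentile (robust spread), excess kurtosis of depths (noise/skew
  indicator), and the 75th-percentile depth again as a scene-distance
  proxy.  These target skewed camera placements (head's/foot's end) and
  noisy streams.

Invariants: the graded features are non-increasing along their threshold
lists; scaling all depths by *c* scales the spatial-scale group by exactly
*c*²; all 16 values are finite on any frame the cascade can emit,
including fully invalid ones (sentinel 0, kurtosis 0 below 4 valid
pixels).  Kurtosis uses the Fisher (excess) convention with the biased
(population) estimator so Gaussian noise sits at 0.

### Classifier

A random forest of CART trees (Gini impurity), each grown on a bootstrap
sample with a random subset of features considered per split; the motion
probability is the mean of the per-tree class-1 probabilities.  Defaults:
100 trees, 4 of 16 features per split, unlimited depth.  A second is
flagged as motion when its probability *strictly* exceeds the operating
threshold.  Tree growing is delegated to scikit-learn; this package pins
seeding, feature-order validation, persistence (model files embed the
forest/feature/denoise configurations and the feature ordering, and refuse
to predict on mismatched columns) and the ensemble contract.

Hyperparameters and denoising parameters can be optimized jointly by grid
search maximizing the mean over held-out clips of √AUC — a concave
transform that penalizes weak clips more than it rewards strong ones.

### Evaluation protocol

Per-subject leave-one-out with threshold transfer.  For each held-out
subject: train on all other subjects' pooled seconds; build the training
ROC from the model's probabilities on that pooled data; select the
threshold maximizing (sensitivity + specificity)/2, ties toward the lower
threshold; apply model and threshold unchanged to each of the held-out
subject's positional clips separately.  Reported: per-clip test AUC
(trapezoidal, equal to the Mann–Whitney concordance statistic) and
sensitivity/specificity at the transferred threshold; summaries are means
and sample (n−1) SDs over clips.  Clips whose truth labels are
single-class have no defined ROC and are excluded from metric summaries
(logged, still listed).  Subgroup tables split per-clip AUC by bed type,
cover type, camera location, or term/preterm (> 37 weeks / ≤ 37 weeks).

## Synthetic scenes

No study recordings are distributed, so the `synthetic` module renders
labelled clips with the structure the method assumes.  A scene is a flat
cot surface at 950 mm; a neonate-like half-ellipsoid body bulging toward
the camera (chest at 230–800 mm — the study's placement range); static
low-frequency relief on the body (25 mm RMS, ~28 px correlation length)
standing in for bedding folds and limbs; near clutter (two corner
"nesting rolls" ~80 mm closer than the chest, ~8 % of the frame);
breathing (2 mm, 50 breaths/min over a chest sub-ellipse); motion events;
and sensor noise (Gaussian jitter 0.5 mm at 300 mm growing to 2 mm at
900 mm, 0.5 % dropouts, sparse outliers).  Depths are quantized to integer
millimetres; dropouts are written as 0.

Events arrive as a Poisson process (3/min), each an elliptical bump
(50–500 px, 5–120 mm peak) with a 0.3 s half-cosine onset/offset ramp, a
piecewise-linear random height trajectory, and a lateral wander of the
bump centre (control points every 0.5 s).  The truth label for second *t*
is 1 iff an event is active somewhere in [*t*, *t*+1] — the same alignment
rule the feature extractor uses.  With these defaults about 18 % of
seconds are motion.

Two generator choices deserve emphasis because they interact with the
percentile clip:

* **Events translate rather than only plunge.**  A patch that moves purely
  toward the camera by its full amplitude dives below the scene's
  3rd-percentile depth and is invalidated — the clip stage cannot tell a
  limb 100 mm closer from near clutter.  Real limb motion is largely
  lateral in the image plane; the wandering bump reproduces that and keeps
  the moving surface inside the percentile band.
* **The scene must contain structure nearer than the chest.**  The
  percentile clip exists to strip near and far non-neonate depths.  In a
  scene where the body apex is the global minimum, the 3rd-percentile cut
  erases the apex — the very place motion happens.  The corner clutter
  gives the cut its intended prey.

What the generator does **not** model: camera projection (patch sizes do
not shrink with distance), occlusion by caregivers, RGB appearance,
structured artefacts of isolette covers, autonomic movements
(startles/tremor), or imperfect manual labelling — truth labels come from
the event schedule itself, an idealization of visual scoring.  Because
projection is not modelled, the only distance-dependent degradation is
the depth-scaled sensor noise; with events of 5–120 mm against sub-mm
post-filter noise, the near-vs-far AUC gap is real but small (on the
order of half an AUC point), much weaker than the drop-off a real system
shows beyond ~640 mm, where projection shrinks limbs toward the region
filter's 40 px floor.  Passing the
synthetic acceptance experiments therefore demonstrates that the pipeline
recovers motion of the assumed scale/statistics under the assumed noise;
it does not certify clinical performance.

A known residual failure mode, observed both here and in the clinical
report's spread: the four depth-summary features are near-constant within
a clip, so a held-out clip whose depth statistics fall outside the
training support can see its *transferred threshold* misbehave (per-clip
specificity collapsing toward 0) even while its within-clip ranking — the
AUC — stays high.  The per-clip AUC SD and sensitivity/specificity SDs in
the leave-one-out report surface this.

## Numerical choices

* Percentiles: `np.percentile` linear interpolation between order
  statistics, used identically everywhere (the estimator was unstated in
  the source description).
* Percentile clipping is recomputed per averaged frame, not once per clip.
* Masked medians: value = median of valid window entries (mean of the two
  middle order statistics for even counts); a pixel's validity never
  changes in the filter stage, so the cascade's valid-pixel count is
  non-increasing through the cleaning stages.
* ROC sweep: thresholds are −∞ plus the unique probabilities; the strict
  `>` rule makes the largest probability the all-negative end.  AUC by
  trapezoid over (1 − specificity, sensitivity).
* Ties in optimal-threshold selection go to the lowest threshold (highest
  sensitivity); ties in grid search to the smaller model (fewer trees,
  then shallower).
* Determinism: every entry point takes one seed; per-fold and per-clip
  seeds are spawned from it via `numpy.random.SeedSequence`.

## Problem sizes used in the automated experiments

The end-to-end experiments run a reduced synthetic study of 8 subjects ×
3 clips × 120 s at the default 240×320 scene (≈ 2 900 labelled seconds),
and the distance experiment renders 100 s clips at 120×160 with
proportionally scaled body geometry at 300 mm vs 900 mm over 5 seeds.
These sizes were chosen so the whole suite runs comfortably on a single
CPU while keeping per-clip second counts large enough for stable ROC
estimates; the protocol itself is identical at any scale.
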