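# neomotion

Non-contact neonatal activity monitoring from depth-camera video.

Neonatal activity is a clinically meaningful signal in the NICU — lethargy
is associated with sepsis onset and over-sedation, restlessness with pain
and under-sedation — and motion is simultaneously the main source of
artefact in contact-based vital-sign monitoring.  A depth camera above or
beside the cot delivers a raster of distances (mm) to every surface in
view at 30 fps, with no sensor on the infant.  `neomotion` converts such a
stream into a per-second **motion / no-motion** classification:

1. **Temporal median averaging** — one median frame per 1 s span boundary
   (10 frames each), robust to speckle;
2. **Denoising cascade** — percentile clipping (keep depths between the
   3rd and 87th percentile of the 200–1000 mm band, i.e. the neonate),
   1 s depth differencing, 5×5 and 3×3 masked spatial median filters,
   removal of |Δ| > 150 mm (too large to be neonatal motion) and of active
   regions < 40 px (too small);
3. **16 time-variant features** per second — graded-threshold area
   fractions (spatial scale of motion, distance-normalized by
   (mean depth/500 mm)²), graded-threshold summed |Δ| (motion magnitude),
   order-statistic depth summaries, and a spread/kurtosis/distance "skew"
   set for angled camera placements;
4. **Random forest** — bagged CART trees on random feature subsets; the
   motion probability is the mean per-tree class-1 probability, and a
   second is flagged when it strictly exceeds the operating threshold;
5. **Per-subject leave-one-out evaluation** — train on all other
   subjects, pick the threshold maximizing (sensitivity+specificity)/2 on
   the training ROC, transfer it unchanged to every positional clip of the
   held-out subject, and report per-clip ROC-AUC and operating-point
   sensitivity/specificity.

No clinical recordings ship with the package; a first-class synthetic
scene generator (`neomotion.synthetic`) renders labelled depth clips with
the geometry, breathing, motion statistics and depth-sensor noise the
method assumes, so the entire pipeline is exercisable offline.  See
`docs/methods.md` for the model, its assumptions, and what the synthetic
experiments do and do not demonstrate.

## Worked example

```python
import numpy as np
from neomotion import (
    ForestConfig, SceneConfig, build_dataset, generate_study, loocv,
)

# a small synthetic study: 4 subjects, 2 camera placements each, 60 s clips
scene = SceneConfig(duration_s=60.0, frame_shape=(120, 160),
                    body_axes_px=(45.0, 65.0), chest_axes_px=(15.0, 21.0),
                    relief_scale_px=14.0)
clips = build_dataset(generate_study(4, 2, seed=7, scene=scene))
report = loocv(clips, ForestConfig(), seed=3)
print(report.per_clip[["clip_id", "distance_mm", "auc",
                       "sensitivity", "specificity"]].round(3))
print({k: round(v, 3) for k, v in report.summary.items()})
```

Output:

```
  clip_id  distance_mm    auc  sensitivity  specificity
0  S01C01      672.141  1.000        1.000        1.000
1  S01C02      401.095  1.000        1.000        1.000
2  S02C01      684.330  1.000        1.000        1.000
3  S02C02      402.728  0.983        1.000        0.974
4  S03C01      517.593  0.927        0.857        1.000
5  S03C02      797.435  1.000        1.000        1.000
6  S04C01      352.726  0.867        0.800        1.000
7  S04C02      579.148  1.000        1.000        1.000
{'mean_auc': 0.972, 'sd_auc': 0.049, 'mean_sensitivity': 0.957,
 'sd_sensitivity': 0.081, 'mean_specificity': 0.997, 'sd_specificity': 0.009,
 'mean_threshold': 0.283, 'sd_threshold': 0.089, 'n_clips': 8, 'n_excluded': 0}
```

Each row is one positional test run of a held-out subject: `auc` is the
area under its test ROC curve and `sensitivity`/`specificity` the
operating point at the threshold transferred from that fold's training
ROC.  The summary gives the mean and sample SD over clips, plus the mean
training threshold across folds.

The same pipeline is available from the shell — every stage is a
subcommand driven by one YAML config:

```bash
neomotion simulate -c run.yaml          # render a synthetic study to disk
neomotion extract  -c run.yaml          # denoise + feature CSVs per clip
neomotion evaluate -c run.yaml          # leave-one-out report (+ plots)
neomotion train    -c run.yaml          # one forest on all seconds
neomotion predict  -c run.yaml dataset/clips/S01C01.npy -o probs.csv
neomotion grid-search -c run.yaml       # forest x denoise grid search
```

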