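# mbassay

Automated, frame-resolved analysis of the mouse **marble-burying test**.

The classical readout of this assay — an experimenter counting how many
marbles are more than 50% (or two-thirds) covered at the end of a 30-minute
session — discards everything about *when*, *where* and *for how long* the
animal actually buried. `mbassay` re-implements the full automated pipeline
for a standard top-down recording setup (26.6 × 42.5 cm cage, 25 fps, 20
blue marbles in four rows):

1. **Tracking** — median-background subtraction, Otsu thresholding, largest
   connected component, body ellipse from second-order image moments
   (centroid `(x, y)`, axes, orientation θ ∈ [0, π)).
2. **Frame classification** — per-frame kinematic features (speed,
   acceleration, turn rate, ellipse shape, wall/corner distances, local
   pixel change) expanded into sliding-window statistics
   (mean, σ, min, max, Δ at radii {2, 6, 12} frames) and fed to a boosted
   ensemble of depth-≤2 trees; every frame gets a burying margin
   s<sub>t</sub>, labeled burying when s<sub>t</sub> ≥ 0.
3. **Bout statistics** — maximal runs of burying frames, gap-merged then
   filtered at a 1-s minimum bout length; count, mean duration, total
   burying time, duration histograms and cumulative 1-min-binned curves.
4. **Activity & topography** — distance traveled and mean speed in cm,
   burying vs non-burying occupancy heatmaps, corner preference.
5. **Marble coverage** — HSV color thresholding of end-of-test photographs,
   per-marble visible area, coverage fraction `1 − visible/baseline`, and
   buried calls at the 50% / two-thirds conventions.
6. **Agreement & group statistics** — observer/classifier 2×2 frame
   confusion, and the normality-gated comparison procedure
   (D'Agostino–Pearson or Shapiro–Wilk at α = 0.05 deciding between
   t / Mann-Whitney and paired-t / Wilcoxon, exact rank nulls at small n).

A synthetic-data generator (`mbassay.synthetic`) produces confined
random-walk trajectories with corner-biased low-speed burying epochs,
rendered frame stacks, marble images with known per-marble occlusion, noisy
observer labels and Gaussian feature tables — so every stage has a
parameter-recovery test surface with exact ground truth.

## Worked example

```python
import numpy as np
import mbassay as mb
from mbassay.tracking import ArenaGeometry

# simulate a 2-minute session and render it to video frames
spec = mb.SessionSpec(duration_s=120, fps=25, n_bouts=6, seed=11)
track_true, truth = mb.make_trajectory(spec)
stack = mb.render_frames(track_true, spec, noise_sd=3.0, seed=11)

# track, featurize, train on the ground-truth labels
bg = mb.estimate_background(stack, sample_stride=10)
track = mb.track_frames(stack, bg)
arena = ArenaGeometry.from_rect(spec.arena_w_px, spec.arena_h_px)
wf = mb.windowize(mb.compute_frame_features(track, arena, frames=stack))
model = mb.train_classifier(wf, truth.labels, seed=0)

# score a held-out session end to end
spec2 = mb.SessionSpec(duration_s=120, fps=25, n_bouts=6, seed=12)
track2, truth2 = mb.make_trajectory(spec2)
stack2 = mb.render_frames(track2, spec2, noise_sd=3.0, seed=12)
model.save("burying.joblib")
cfg = mb.SessionConfig(model_path="burying.joblib", arena=arena)
bundle = mb.run_session(cfg, frames=stack2)
s = bundle["bout_summary"]
print(s.n_bouts, round(s.total_burying_s, 1),
      round(mb.summarize_bouts(truth2.bouts).total_burying_s, 1))
```

prints

```
6 59.5 59.6
```

— the pipeline recovers all 6 generated bouts and estimates 59.5 s of
burying against a ground truth of 59.6 s; frame-level agreement with the
generator labels is 99.6% on this session.

The same flow is available from the shell:

```bash
mb simulate session --duration 120 --n-bouts 6 --seed 11 --render --out sess/
mb track --video sess/frames --out track.csv
mb bouts --labels sess/labels.csv --fps 25 --min-bout 1.0
mb marbles --image after.png --threshold 0.667 --expected 20
mb compare --data cohort.csv --metric total_burying_s --tails 1
```

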