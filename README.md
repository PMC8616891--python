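# suturepoint

Multi-instance heatmap regression for detecting **suture entry/exit
points** in endoscopic images of mitral valve repair.

During annuloplasty, sutures are placed around the valve annulus; locating
each thread's entry and exit point in the endoscopic video provides
quantitative information for analysing suturing patterns, assessing
prosthetic ring configurations, and driving augmented-reality overlays.
Unlike facial or anatomical landmarking, every frame contains a *variable*
number of interchangeable points — often in pairs only a few pixels apart —
so fixed-output regression is ill-posed. This package is for researchers in
surgical data science who need a point detector for this multi-instance
regime, together with the matching-based evaluation protocol that goes with
it.

## Method

All point instances are encoded jointly in a single likelihood channel: a
radial profile — Gaussian `exp(-d²/2σ₁²)` or the sharper
`1 − tanh(d²/α)`, with `α = 3.5σ` — is centred on each point and
overlapping profiles combine by pixel-wise maximum. A U-Net with a
sigmoid single-channel head predicts this map, followed by two
differentiable layers:

* a **Gaussian filter** of spread σ₂ (output stage 1), encouraging a
  smooth likelihood distribution around each predicted location;
* a **convolutional 2-D spatial soft-argmax** (3×3 window, stride 1,
  output stage 2), `out(p) = Σ_q softmax(x_{N(p)}/T)_q · x_q`, which acts
  as a differentiable local non-maximum suppression.

Training minimises `L₁ + L₂` with Adam (lr 0.001, reduce-on-plateau
0.1/10): `L₁ = MSE + 1 − SDC` on stage 1, and on stage 2 either the same
loss against the heatmap (**variant 1**) or `1 − F_β` against the binary
point mask with β = 2 (**variant 2**), which weighs recall β² times
precision to fight the extreme pixel imbalance. Predicted maps are decoded
by thresholding at 0.5 and taking the intensity-weighted centre of mass of
each connected component.

Evaluation matches predictions to ground truth greedily, closest pair
first, within a radius (6 px; sweeps at 6/8/10), yielding TP/FP/FN and
PPV/TPR/F1 = 2PR/(P+R), plus a localisation RMSE over predicted points
with explicit accounting of images that have no predictions, close-point
(< 15 px) subset analysis, and group-wise cross-validation aggregation.

Everything — including the U-Net, both custom layers and Adam — runs on a
small reverse-mode autodiff core over numpy arrays (`suturepoint.autograd`),
so the whole pipeline is dependency-light, deterministic on CPU, and
verifiable against brute-force oracles. A synthetic endoscopy-scene
generator (reddish tissue, vignette, specular distractors, curved threads
whose endpoints are the ground truth, controllable close-pair fraction)
provides seeded data for experiments and tests.

## Worked example

```python
import numpy as np
from dataclasses import replace
from suturepoint import (SceneSpec, generate_scene, RunConfig, ModelConfig,
                         DistributionSpec, SutureDetectionModel)

# 230 synthetic endoscopy scenes, 96x160, 4-10 suture points each,
# 20% of points in close pairs (< 15 px)
scene = SceneSpec(height=96, width=160, n_points=(4, 10),
                  close_pair_fraction=0.2, seed=100)
seeds = np.random.SeedSequence(100).generate_state(230)
data = [generate_scene(replace(scene, seed=int(s % 2**31))) for s in seeds]
images = np.stack([d[0] for d in data])
points = [d[1] for d in data]

config = RunConfig(
    model=ModelConfig(input_height=96, input_width=160, depth=3,
                      base_filters=8, sigma2=1.0),
    dist=DistributionSpec("gaussian", sigma1=2.0),
    epochs=10, batch_size=8, seed=1)

model = SutureDetectionModel(images[:200], points[:200], config)
results = model.fit()
print(results.summary())
report = results.evaluate(images[200:], points[200:])
print(report["metrics"])
```

Output:

```
Suture point detection results
==============================================
U-Net depth / base filters         3 / 8
input size                         96x160
parameters                         29537
encoding                           gaussian (sigma1=2.0)
gaussian layer sigma2              1.0
loss variant                       1
epochs run                         10
best training loss                 0.95604
final learning rate                1.00e-03
==============================================
   radius        ppv        tpr        f1  n_images
0     6.0  95.535714  92.640693  0.940659        30
1     8.0  95.535714  92.640693  0.940659        30
2    10.0  95.535714  92.640693  0.940659        30
```

On the 30 held-out scenes the detector recovers 92.6 % of the planted
suture points at 95.5 % precision (F1 0.94 at the 6 px matching radius);
the remaining misses are dominated by close pairs whose encodings merge
above the decoding threshold — the trade-off the close-point subset
analysis quantifies. Training at this scale is seed-sensitive: some seeds
need more than the 10 budgeted epochs to push blob amplitudes over the
0.5 decoding threshold (see docs/methods.md).

The same pipeline is available from the shell:

```bash
suturepoint generate --out data/train --n-images 200 --height 96 --width 160 \
    --n-points 4 10 --seed 1
suturepoint train --data data/train --out runs/detector --seed 0
suturepoint predict --checkpoint runs/detector --images data/val --out pred.csv
suturepoint evaluate --pred pred.csv --ann data/val --radii 6,8,10
```

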