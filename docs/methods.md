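# Methods

## Problem

Endoscopic frames from mitral valve repair (and from silicone-replica
training simulators) contain a variable number of suture threads; the
quantity of interest is the set of pixel locations where each thread enters
or exits the tissue. Unlike facial or anatomical landmarking there is no
fixed number of targets and no per-landmark identity, so the task is
*multi-instance* 2-D point detection: every image may contain anywhere from
zero to dozens of interchangeable points, often in pairs only a few pixels
apart.

## Model

### Heatmap encoding

All point instances are encoded jointly in one likelihood channel. Each
ground-truth point s contributes a radial profile of its distance d:

* Gaussian: `exp(-d^2 / (2 sigma1^2))`, spread `sigma1` in pixels
  (typical values 1-4; default 2);
* Tanh: `1 - tanh(d^2 / alpha)`, a sharper profile, with
  `alpha = 3.5 * sigma` pairing it to a Gaussian of comparable spread
  (typical values 7, 10.5);
* or a binary mask with a single 1-pixel at each rounded point location.

Overlapping profiles combine by the pixel-wise **maximum**, not the sum.
This is a deliberate design choice: it preserves the [0, 1] likelihood
semantics, keeps the value at each annotated point exactly 1, and keeps the
0.5 decoding threshold meaningful where two encodings overlap. The exact
functional form of the tanh profile and the overlap rule are conventions of
this package; only sharpness ordering and the `alpha = 3.5 sigma` pairing
are externally constrained, and the monotonicity/sharpness properties are
asserted by tests.

### Detector

A U-Net (configurable depth and base width; two 3x3 conv + ReLU per level,
2x max-pool down / 2x2 transposed-conv up, skip connections) maps the RGB
image to a single channel through a 1x1 conv + sigmoid. Two differentiable
layers follow:

1. **Gaussian filter layer** (spread `sigma2`, default 1 px): each map is
   convolved with a unit-mass Gaussian kernel truncated at 3 sigma
   (kernel size `2 ceil(3 sigma2) + 1`, reflect padding). Output stage 1.
   The layer encourages a smooth likelihood distribution around each
   predicted location; sum normalisation plus reflect padding preserve
   constants and interior mass, so values stay in [0, 1].
2. **Convolutional spatial soft-argmax** (3x3 window, stride 1, zero
   padding, temperature 1.0): each pixel is replaced by the
   softmax-weighted average of its window,
   `out(p) = sum_q softmax(x_N(p)/T)_q * x_q`. Output stage 2. Because the
   weights concentrate on the window maximum, the layer acts as a
   differentiable local non-maximum suppression: pixels dominated by a
   brighter neighbour are pulled down relative to the local peak, and the
   output never exceeds the window maximum. The "soft value" form (rather
   than soft coordinates) is the natural choice when all instances share
   one channel; the temperature is fixed and non-trainable.

Both layers are exactly verified against brute-force dense-convolution /
per-window enumeration oracles (max abs difference <= 1e-5) and against
central finite differences for gradient flow (<= 1e-3 relative).

### Losses

Stage 1 is always supervised with `L1 = MSE + 1 - SDC` against the encoded
heatmap, where SDC is the soft Sorensen-Dice coefficient
`(2 sum(p t) + eps) / (sum p + sum t + eps)`. Stage 2 uses either

* **Variant 1**: the same `MSE + 1 - SDC` against the heatmap, or
* **Variant 2**: `1 - F_beta` against the binary mask, with

      F_beta = ((1+b^2) sum(p g)) / ((1+b^2) sum(p g) + b^2 sum((1-p) g) + sum(p (1-g)))

  and `beta = 2`, weighing recall four times precision — false negatives
  are the costly error under the extreme pixel imbalance of single-pixel
  targets.

The joint objective is the unweighted sum `L1 + L2`. Numerical choices:
MSE is averaged (not summed) over pixels so that both L1 terms have
comparable magnitude; a smoothing `eps = 1e-6` is added to the numerator
and denominator of Dice and F-beta, which otherwise are undefined for an
empty target; the Dice/F-beta terms use soft (probabilistic) predictions
for differentiability. With `beta = 1`, F-beta reduces exactly to soft
Dice (asserted to 1e-9).

### Decoding

Predicted stage-2 maps are thresholded at `t = 0.5` (strict `>`), the
surviving pixels grouped into 8-connected components, and each component
reduced to its intensity-weighted centre of mass, giving sub-pixel points.
8-connectivity avoids splitting diagonal blob ridges; strictness of the
comparison is arbitrary and documented here. This decoding makes the
close-point trade-off concrete: two points whose encodings overlap above
the threshold decode as one (e.g. a 2 px pair at sigma1 = 3), while
well-separated points (pairwise distance above roughly the
full-width-half-maximum `2 sigma1 sqrt(2 ln 2)` plus 2 px) round-trip
exactly.

## Evaluation protocol

A prediction matches a ground-truth point when their distance is strictly
below the matching radius (default 6 px; sweeps use 6/8/10). Matching is
greedy closest-first over all candidate pairs: when two predictions compete
for one ground-truth point the closest wins and the other falls through to
its second-best option. Ties are broken by (prediction index, ground-truth
index); the counts always satisfy `tp + fp = |pred|` and `tp + fn = |gt|`.
From TP/FP/FN: PPV and TPR in percent, and `F1 = 2 P R / (P + R)` on the
fractional rates.

Localisation RMSE: each predicted point contributes its minimum distance
to any ground-truth point (reuse allowed), the squared minima are averaged
per image and rooted; images with no predictions cannot be scored and are
reported as a separate count. The metric deliberately mirrors its known
limitation — it does not penalise false positives beyond their own
distance, so two models with different FP counts can share an RMSE.

Close-point analysis partitions ground-truth points into those with a
neighbour nearer than 15 px and the rest, and reports the matched
percentage of each subset per model — the regime where overlapping
encodings confound detection.

Cross-validation is group-wise (a surgery/session never straddles folds):
unique group labels are dealt round-robin to k folds, one model trained
per fold, metrics pooled over the fold's held-out images and aggregated as
mean +/- population standard deviation. The held-out fold is never used
for early stopping, scheduling or checkpoint selection.

## Training

Adam at learning rate 0.001; the rate is multiplied by 0.1 when the
training loss has not improved for 10 epochs. Because the validation fold
must remain unseen, both the plateau detection and the retained checkpoint
(lowest training loss) are driven by the training loss only. Batch size
defaults to 8: the Dice and F-beta terms pool over the whole batch, so
very small batches make their gradients noisy — batch 8 trains markedly
more stably than 4 or 1 in the reference desk-scale experiment. Images
are scaled to [0, 1]; no further normalisation.
Every source of randomness (weight init, shuffling, augmentation) derives
from the run seed, and two runs with the same configuration produce
bit-identical logs and parameters on CPU.

One initialisation choice matters at small scale: convolution weights are
He-normal, but the 1x1 head bias starts at -2.0 so the sigmoid output
begins near the background rate (~0.12) rather than 0.5. On extremely
sparse targets a 0.5 start makes the first optimisation phase a collapse
toward all-background that saturates the sigmoid and kills gradients;
starting near the background level keeps gradients alive and lets blob
amplitudes grow from the first epoch.

The network, the two custom layers, the losses and Adam are implemented on
a small reverse-mode autodiff core over float64 numpy arrays
(`suturepoint.autograd`): a Tensor type recording a dynamic graph, with
broadcast arithmetic, matmul, reshaping, relu/sigmoid/exp, reductions,
concatenation, 2x2 max pooling and a stride-1 sliding-window unfold (zero
or reflect padding) from which the convolutions and both custom layers are
composed. Gradients of every primitive and of the fully composed detector
are verified against central finite differences.

## Synthetic scenes

The generator emulates the properties of annuloplasty endoscopy that the
method is sensitive to, not photorealism: a low-frequency reddish tissue
background, an elliptical field-of-view vignette, bright specular blobs as
distractors, and pale curved suture threads. Each annotated point is the
exact endpoint of one rendered thread, marked by a small dark puncture —
the visual signature of a thread entering tissue. Point layout is
controlled: a configurable fraction of points (default 0.2) is placed in
close pairs 4-14 px apart (one triple when the requested count is odd),
and every other point keeps >= 15 px clearance, so the close/non-close
composition of each scene is exact and recomputable from the returned
ground truth. Default geometry is 288x512 with 5-25 points per image
(matching roughly 10 sutures per frame in the real datasets); the
scaled-down training used by the tests and the acceptance script uses
96x160 scenes with 4-10 points, which keeps per-image point density
comparable.

Augmentation reproduces the standard endoscopy suite: horizontal and
vertical flips, rotation +/-60 deg, affine translation +/-10 %, shear
+/-0.1, additive brightness +/-0.2, contrast factor in [0.3, 0.5] about
mid-grey, saturation scale in [0.5, 2.0], hue shift +/-0.1, additive
intensity shift +/-1 % — each applied independently with probability 0.5.
Geometric transforms are applied identically to coordinates (verified by
encoding-vs-warping consistency to <= 0.05 mean absolute difference);
points carried out of the frame are dropped. Two ambiguous conventions
are resolved as: "pixel shift" is an additive intensity shift (it sits
among the photometric transforms), and contrast is a multiplicative factor
about mid-grey drawn from the stated range.

What the synthetic scenes do **not** capture: real tissue texture and
specular geometry, instrument occlusion, stereo capture, video temporal
structure, white-balance and scale variation between surgeries. Passing
the end-to-end tests therefore demonstrates that the pipeline — encoding,
architecture, losses, optimisation, decoding, matching — is correct and
can learn point detection from images with realistic structural
difficulty (variable counts, close pairs, distractors); it does not
certify performance on real endoscopy, which additionally depends on
dataset scale and domain variability.

## Scaled-down problem sizes

The library defaults target the full 288x512 resolution with a depth-5 /
64-filter U-Net. The test suite and the acceptance script exercise the
complete pipeline at a reduced size chosen as this package's reference
desk-scale experiment: depth-3 / base-8 detector, 96x160 scenes, 200
training + 30 held-out images, 10 epochs, variant 1, sigma1 = 2,
sigma2 = 1, Adam lr 0.001. At this scale a training run takes a few
minutes on one CPU and typically reaches a held-out F1 at 6 px above 0.9;
the outcome is seed-sensitive — a minority of weight-init seeds land in a
slow optimisation basin where blob amplitudes have not crossed the 0.5
decoding threshold after 10 epochs, which reads as near-zero recall at
that budget. Multi-seed reporting (median/best over three seeds) is used
wherever this experiment is summarised. The larger configurations are
exercised for shape/contract correctness only.

## Known limitations

* Heatmap decoding merges points whose encodings overlap above threshold;
  recall on close pairs is intrinsically bounded for larger sigma1.
* The RMSE metric ignores unmatched false positives by construction.
* The matcher's greedy assignment is optimal only in well-separated
  regimes (asserted on small instances against maximum-cardinality
  matching); adversarial distance ties can differ from an optimal
  assignment.
* The float64 numpy implementation favours verifiability over speed;
  GPU-scale training of the full-resolution model is out of scope.
* Anisotropic or per-point adaptive spreads are not supported.
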