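# Methods

## Overview

`genecam` re-implements, as a tested pipeline, a transcriptome-to-image
classification and attribution workflow: bulk RNA-seq expression profiles
are embedded as fixed-length 1-D "gene images" (one pixel per gene), a
small convolutional network classifies tumour type under stratified
10-fold cross-validation, and class-activation heatmaps are mapped back
through the pixel-gene bijection to rank the genes driving each class
("leader genes"). Because the original cohorts are not bundled, a
synthetic generator with planted, known structure provides ground truth
for every stage.

## Synthetic cohorts

For gene g in sample s of class c the generator draws

    x_gs = 2^z - 1,   z ~ Normal(mu_g + shift_gc, sigma),  z truncated at 0,

with per-gene baselines mu_g ~ Uniform(1, 8) on the log2 scale (the span
of typical normalized RSEM counts), noise sigma = 0.5, and shift_gc = 4
(a 16-fold change) for each class's 20 planted marker genes, 0 otherwise.
Counts are therefore log-normal, heavy-tailed and non-negative. The
default cohort has four classes of deliberately unequal size
(60/40/30/20), since real tumour cohorts are unbalanced. One global seed
drives named sub-streams (baseline means, marker placement, noise), so
enlarging one stage never reshuffles another.

The *confusable* preset models two carcinomas of shared tissue origin:
classes 0 and 1 share 18 of their 20 markers and each has two private
genes. The private genes carry a subtle 2-fold shift
(`distinct_log2_shift = 1.0`) rather than the 16-fold shift of cohort
markers: the biology distinguishing two same-origin tumours is a small
expression difference in a handful of genes, not a full marker program.
Under the default variance threshold those subtle genes do not survive
filtering, so the two classes become identical in the model's view and
the minority class is largely absorbed by the majority one - the
mechanism behind the shared-origin misclassification pattern this
scenario exists to reproduce. With full-strength private markers the
pair is trivially separable and the scenario is vacuous.

What the generator does **not** emulate: read-level sampling,
library-size variation, batch effects, gene-gene correlation beyond the
planted class structure, down-regulated markers (directions are
configurable but default to up-shifts), or clinical covariates. Passing
tests therefore demonstrate that the pipeline recovers planted structure
under idealized noise - not that it would reach any particular accuracy
on real tumours.

## Preprocessing

1. Transform y = log2(x + 1).
2. Keep genes whose population variance (ddof 0) of y across the
   in-scope samples is **strictly** greater than the threshold
   (default 1). The filter runs on transformed values.
3. Lay retained genes on the image ordered by descending variance,
   ties broken lexicographically by gene id; if more genes survive than
   pixels, the lowest-variance excess is dropped (and counted in the run
   log). Trailing pixels are padding.
4. Scale intensities by global min-max over all in-scope retained
   y-values onto (0, 1), clipping out-of-range values; padding pixels
   carry the scaled value of y = 0. A degenerate range (max = min) maps
   everything to the lower bound. Scaling is global, not per gene, so a
   pixel's intensity remains monotone in its count and comparable across
   pixels.

Two scopes exist: `all_samples` (default) fits the filter, layout and
scaler on the whole dataset, mirroring whole-cohort preprocessing;
`train_only` refits them on each cross-validation training fold, the
leakage-free variant. The label-permutation control bounds what the
default scope's mild leakage can contribute.

The default image length is 1152: with three 'same'-padded conv stages,
pool width 2 and 256 final channels the flattened feature count is
1152/2/2/2 x 256 = 36,864, which pins the network's first fully
connected size.

## Network and training

    [conv1d(kernel 7, stride 1, 'same') -> ReLU -> max-pool(2) -> batch-norm] x 3
        with 64, 128, 256 filters
    -> dropout(0.25) -> flatten
    -> FC 1024 -> FC 512 -> FC 256 (ReLU) -> FC n_classes -> softmax

Max-pooling floor-divides the spatial axis (a remainder column is
dropped), and the model derives its FC input size from the configured
image length, so any geometry is consistent by construction. Training
minimises cross-entropy with Adam (lr 1e-3, batch 32, default 50
epochs). Kernel size, pool width, learning rate, epochs and batch size
are exposed in the config.

The layers are implemented directly on numpy (im2col convolutions with
BLAS matmuls, hand-derived gradients, float32 by default). Backprop
correctness is checked against float64 central differences in the test
suite, and the attribution path is additionally anchored by an occlusion
oracle (below). Everything is deterministic given the seeds: same seed,
same inputs, bit-identical training history and reports.

Cross-validation is stratified (class proportions per fold within one
sample), since cohorts are unbalanced; each fold trains a freshly
initialised model and scores only its held-out samples, so every sample
is predicted exactly once. "Training accuracy" is the final-epoch
minibatch accuracy averaged over folds. Headline precision/recall/F1 are
macro (unweighted over classes); per-class values undefined for a
never-predicted class are reported as absent and excluded from macros
with a warning rather than set to 0.

## Class activation maps

The classic CAM construction requires global average pooling feeding a
single FC layer, which this architecture lacks, so a gradient-weighted
generalization is used. Let A (channels x positions) be the last
convolutional stage's rectified, max-pooled activations - non-negative,
at the coarse resolution of image_length/8 - and G the gradient of the
target-class logit with respect to A (the batch-norm that follows A is,
in evaluation mode, a per-channel affine map, so the gradient passes
through it exactly). The coarse map is the element-wise
positive-gradient weighting

    coarse[l] = relu( sum_c relu(G[c, l]) * A[c, l] ),

normalized per map so its maximum is 1 (all-zero maps stay zero). The
element-wise form (Layer-CAM style) is used instead of spatially
averaged channel weights (grad-CAM style) as a deliberate design choice:
with the maps flattened into an FC head, one channel can carry
positively and negatively signed evidence at different positions, and a
single spatially averaged weight cancels or even inverts it - in
diagnostic runs the averaged-weight variant produced all-zero or
occlusion-anticorrelated maps while the element-wise form tracked the
occlusion oracle and the planted markers. Negative evidence is discarded
(double ReLU), matching standard CAM-style visualisation.

Coarse maps are upsampled to pixel resolution by linear interpolation
between pooled-grid pixel centers, converted to per-gene scores through
the layout (padding pixels are skipped), and averaged over a class's
held-out samples, each scored by the fold model that never trained on it
(memorized attributions are thereby excluded). Per-map normalization
before averaging keeps large-logit samples from dominating. The top 20
genes by aggregated score (lexicographic tie-break) form the multiwise
leader list; pairwise lists from the focal class's two-class runs are
combined by intersecting each ranking's top `pool_depth` (500) genes and
ordering by mean rank. The multiwise and pairwise routes may legitimately
disagree - they ask different questions of the model - and no test
asserts agreement.

## Occlusion oracle

`occlusion_importance` is the brute-force check of the maps: the drop in
target-class probability when a window of pixels is set to the
scaled-zero padding value (window 1 by default). In the agreement study
the oracle runs with window = 8, the cumulative pooling stride: a map
pooled three times cannot represent structure finer than 8 pixels, and
under variance ordering marker pixels of opposite classes interleave at
single-pixel distance, so probing one pixel at a time measures a spatial
scale the map does not have. Window importances are averaged back onto
the pixels they cover, both attributions are averaged over all held-out
focal-class samples, and agreement is summarised as the Spearman rank
correlation over non-padding pixels. The fixture trains 12 epochs - to
the accuracy plateau but short of softmax saturation, where probability
differences lose dynamic range and the probe degenerates to float noise.

## Study scales

The verification studies (in `genecam.experiments`, shared by the test
suite and `scripts/acceptance.py`) run at desk scale, chosen so a full
10-fold study takes a couple of minutes on one CPU: 128-pixel images and
15 training epochs for the 4-class pipeline studies (under the default
variance threshold only the ~80 planted markers survive filtering, so a
128-pixel image holds every retained gene), and 256-pixel images with a
0.15 variance threshold for the attribution study (so the image is fully
gene-occupied and the oracle comparison has full spatial support). The
label-permutation control on the 60/40/30/20 cohort is expected near
chance; note that a majority-class predictor would reach 0.4, so values
above the 4-class uniform 0.25 are not by themselves evidence of
leakage.

## Numerical notes

* Population (ddof 0) variance everywhere; the filter boundary is strict
  (variance exactly equal to the threshold is removed).
* Argmax prediction ties resolve to the lower class index.
* Softmax rows are computed in float64 and sum to 1 within 1e-6.
* Heatmap normalization divides by the per-map maximum unless it is 0.
* Occlusion of a padding pixel is exactly 0 by construction (the intact
  image rides in the same forward batch as its occluded variants).
* Adam uses the standard bias correction, folded into the step size.

## Known limitations

* The numpy network is CPU-only and unoptimised beyond BLAS matmuls;
  image lengths in the thousands train slowly.
* Vanilla spatially-averaged grad-CAM is not offered; only the
  element-wise construction is implemented.
* The generator's independence across genes makes variance ordering and
  marker recovery cleaner than on real, correlated transcriptomes.
* `extract` (the CLI checkpoint-reload path) supports the default
  `all_samples` preprocessing scope only.
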