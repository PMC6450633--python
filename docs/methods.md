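# Methods

This note documents the models, algorithms and numerical choices in
`expgrad`: a compact CNN for 4-class retinal OCT B-scan classification and
the Expressive Gradients (EG) attribution method that localizes lesions
from image-level labels alone.

## The classification model

The network maps a 128 × 342 × 3 image (values in [0, 1]) to four
independent sigmoid scores, one per class: normal, dry AMD, wet AMD under
observation, and wet AMD requiring anti-VEGF injection.  The architecture
is three convolutional blocks — a 3×3 padded ("same") convolution, a 3×3
unpadded ("valid") convolution, then 2×2 max pooling with stride 2 — with
per-conv output channels (16, 16, 32, 32, 64, 64), followed by flattening
and dense layers of width 200, 20 and 4.  Batch normalization follows the
200-unit layer; dropout at rate 0.5 is applied on the last two dense
connections; all hidden activations are ReLU.  The spatial trace is

    128×342 → 126×340 → 63×170 → 61×168 → 30×84 → 28×82 → 14×41,

giving a flattened width of 14·41·64 = 36 736 and a parameter count of
7 423 984 — roughly 20× fewer than a VGG16-class network, which keeps
gradients informative for attribution.

Channel sizes beyond the third conv layer's (16/32) pair are an open
design point; the doubling plan above is the package default and is
configurable in `ModelSpec`.  Odd spatial dims are floor-divided by the
pooling; the lost row/column receives zero gradient.

Training uses per-class sigmoid cross entropy against one-hot targets (a
softmax variant is available behind `TrainConfig.loss`), the Adam
optimizer, Xavier-uniform initialization, and the reference schedule of
200 epochs (100 at lr 0.01, 50 at 0.001, 50 at 0.0001) with batch size
101.  Quick studies pass shorter schedules.  Everything — weight init,
shuffling, dropout masks — is driven by one seed; two runs with the same
seed are bit-identical.  The network stack (im2col-free shift-matmul
convolutions, explicit backprop, Adam) is implemented directly on NumPy's
BLAS; a training step on a 16-image batch takes ≈2 s on one CPU core.

Two practical details matter for short schedules.  First, batch-norm
running statistics accumulated with momentum 0.9 lag far behind the
weights when training is only a few hundred steps of rapid change; the
train/eval mismatch can cost tens of accuracy points.  `train_model`
therefore refreshes the running statistics after the schedule with the
exact activation moments over (by default) 256 training images
(`TrainConfig.bn_recalibrate`).  Second, on the imbalanced phantom mix the
per-class sigmoid loss spends its first few hundred steps learning the
class prior before features move the argmax; softmax cross entropy
converges roughly twice as fast to the same accuracy, which is why the
end-to-end study selects `loss="softmax_ce"` while the package default
remains the sigmoid form.

## Integrated Gradients and the layer-wise extension

For a class score F_c and baseline b (black image), Integrated Gradients
is the path integral

    IG(x) = (x − b) ⊙ ∫₀¹ ∂F_c(b + α(x − b))/∂x dα,

approximated by a right-endpoint Riemann sum over `steps` points
(α = k/S, k = 1..S; default S = 50).  IG satisfies completeness:
ΣIG ≈ F_c(x) − F_c(b); the acceptance suite verifies a relative gap
< 5 % at 50 steps and < 1 % at 300 steps on a trained toy CNN.

The layer-wise attribution of conv layer i applies the same construction
to the feature map f_i, scoring with the partial network F_{i+1} (all
layers after conv i):

    EG_i(f_i) = (f_i − b_i) ⊙ ∫₀¹ ∂F_{i+1}(b_i + α(f_i − b_i))/∂f_i dα.

Because the formula reuses a baseline of f_i's shape, the package takes
b_i as the black image's own feature map at layer i (an all-zeros feature
baseline is available via `EGConfig.layer_baseline`).  At i = 0 (the input
image) this reduces exactly to IG.

## Projection to input coordinates

A layer attribution has d_i channels and reduced spatial dims; to fuse it
with the input-level map it is walked back to 128 × 342 × 3:

* across a conv layer, channels are mixed by the kernel-marginalized
  weight matrix wg[c_out, c_in] = Σ_{m×m} W[c_out, c_in, ·, ·]; walking
  through a valid (unpadded) conv additionally zero-pads one pixel per
  side to restore the spatial dims;
* across a pooling layer, the map is copy-unpooled: each value is
  replicated over its entire 2×2 receptive block (no argmax indices), so
  high-level relevance is preserved across all receptive positions; when
  the pre-pool dim was odd, one zero row/column is appended.

The walk applies the per-layer wg matrices stepwise so that unpooling
interleaves correctly; on pool-free all-same-padding models it provably
equals multiplying by the precomputed cumulative product
W_i = wg_i · wg_{i−1} ⋯ wg_1 ∈ R^{d_i×3}, which the tests use as an
independent cross-check.

## Expressive Gradients fusion

    EG = Σ_{i=0..L} β_i · N( project(EG_i(f_i)) ),

where N is min-max normalization of the whole map to [0, 1] (a constant
map normalizes to zeros) and L = 6 for the default model.  The default
weights β = [1, 0.166, 0.166, 0.166, 0.166, 0.166, 1] put full weight on
the input-level map (fine spatial detail) and the deepest map (semantic
localization) and 0.166 on the intermediate levels.  Normalization is
applied over the whole projected map, not per channel.  With β = e₀ the
fusion reduces elementwise to N(IG), which the tests assert to 1e−6.

Min-max normalization of a signed map has a known failure mode: one large
negative outlier shifts the zero point so the entire near-zero bulk of the
map lands at 0.3–0.9 after scaling, and downstream thresholding then
marks most of the image hot.  `EGConfig.level_norm = "positive"` makes
N normalize only the positive part of each projected map (negative pixels
are discarded by the localization rule anyway), which keeps zero relevance
at zero.  The default remains the signed form, which preserves the exact
EG = N(IG) reduction at β = e₀; the end-to-end study uses the positive
form.

Guided backpropagation is provided as the standard comparator: one
backward pass in which every ReLU zeroes the signal where either its
forward activation or the incoming backward signal is negative.

## Localization and metrics

The heat map is the positive part of the fused attribution, channel-mean
reduced and min-max normalized.  Pixels with heat strictly greater than
τ (default 0.3) are "hot"; a disc of radius 10 px is grown around every
hot pixel, overlapping discs merge into 8-connected components, and each
component's tight bounding rectangle becomes a proposal scored by the sum
of heat inside it.  Boxes are ranked by (score desc, row_min, col_min) so
top-k selection is deterministic.  The disc radius and the merge rule are
package choices (they must be explicit to be reproducible); τ and the β
defaults follow the method's reference values.

Localization quality against ground-truth boxes uses pixel-level set
metrics on the rasterized unions:

    coverage = N_px(proposed ∩ ground) / N_px(ground)      (recall)
    hit rate = N_px(proposed ∩ ground) / N_px(proposed)    (precision)

Boxes use 0-based half-open coordinates, so a box's pixel count is
(row_max − row_min)(col_max − col_min).  coverage(A, B) = hit_rate(B, A)
by construction.  Images with an empty ground set (or empty proposals,
for hit rate) have that metric undefined; dataset aggregation reports
per-image means and standard deviations over the defined cases plus the
excluded count.  Aggregation is per-image, not per-box.

## The phantom generator

Clinical OCT data is not distributable, so the package ships a seeded
phantom generator that emulates the geometry the classifier must exploit:
a dark background (0.05), one bright (0.8) smoothly curved horizontal
band of Gaussian cross-section (σ = 7 px) standing in for the retinal
layer complex, Gaussian pixel noise (σ = 0.02), rendered identically into
the three RGB channels.  Lesions are implanted per class: dry AMD gets
1–4 small bright bumps on the band's lower edge (drusen-like); wet AMD
(observation) gets 1–2 small dark intra-band cavities (fluid-like);
wet AMD (injection) gets 2–4 larger cavities plus one broad bright dome
under the band (detachment-like).  Every lesion's tight bounding box is
recorded, so localization can be scored against exact ground truth.  The
default class mix (0.502, 0.220, 0.064, 0.213) mirrors the clinical class
imbalance of the reference cohort.

The phantoms are analytic shapes: they contain no speckle, no vessel
shadows, no annotation ambiguity, and their lesion/background contrast is
cleaner than real OCT.  Passing the end-to-end study therefore shows the
*pipeline* is correct and that EG localizes learnable evidence — it does
not certify clinical performance.

## The end-to-end phantom study

`expgrad.pipeline.phantom_study` trains the default architecture on 800
phantoms (image-level labels only; 200 held-out), then scores lesion
localization on 50 lesion-bearing test images three ways: EG (τ = 0.3,
default β), guided backpropagation, and a chance baseline in which the EG
heat map is spatially permuted before thresholding.  It reports held-out
accuracy, mean coverage/hit rate per method, and a paired one-sided
Wilcoxon p-value for EG coverage exceeding the shuffled baseline.

Problem sizes and settings are chosen to keep the study desk-scale on one
CPU core and statistically interpretable:

* training: softmax loss, batch 16, six epochs at lr 3·10⁻³ then two at
  1·10⁻³, batch-norm recalibration — about 12 minutes, reaching ≈0.89
  held-out accuracy, versus the 200-epoch reference protocol;
* EG with 16 Riemann steps (the 50-step default changes per-image
  coverage by far less than the between-image spread);
* disc radius 4 px rather than the real-image default of 10 px: phantom
  lesions are 6–30 px wide, and a 10 px radius makes every proposal at
  least 21 px wide — larger than most lesions, so all proposals merge into
  image-scale rectangles and the coverage metric stops discriminating;
* per-level `level_norm="positive"` (see above), without which some
  images have >90 % of pixels above τ.

One comparison stays degenerate by construction: even the well-trained
model keeps a few percent of pixels above τ = 0.3 (the black-baseline
(x − b) factor concentrates attribution on the whole bright band, ~10 %
of the image).  Thousands of shuffled hot pixels, disc-grown and merged,
produce bounding rectangles that blanket the image, so the shuffled-heat
null attains essentially the same coverage as EG and the paired test has
no power at these settings — the corresponding acceptance test documents
this.  The EG-versus-guided-backpropagation ordering is unaffected.
The acceptance script reruns the whole study from scratch at the given
seed.

## Numerical choices and edge cases

* Right-endpoint Riemann rule for the path integral; the α = 0 endpoint
  contributes a zero integrand factor anyway at a black baseline.
* Attribution gradients are taken through the sigmoid class score (not
  the logit); max-pool backward routes to the first maximum in a window.
* Min-max normalization of a constant map returns zeros (degenerate
  range).
* Thresholding is strict (heat > τ), so τ = 1 selects nothing.
* Images whose size differs from the model input are bilinearly resized
  on load.
* Predict ties break toward the lowest class index.
* All randomness flows from explicit seeds through
  `numpy.random.Generator`; no global RNG state is touched.

## Known limitations

* Sequential architectures only: no skip connections or inception blocks
  in the projection walk.
* The per-class sigmoid head means scores need not sum to 1; argmax is
  still well defined, but calibrated probabilities are out of scope.
* The phantom generator does not model OCT speckle statistics, raster
  scan geometry, or lesion subtypes beyond the bright/dark dichotomy.
* CPU-only: no GPU path; attribution at the 50-step default costs a few
  seconds per image at full resolution.
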