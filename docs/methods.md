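# Methods

## Problem and pipeline

The package segments RGB field images of soybean stands into four
classes: background (soil, stones, straw), soybean, grass weed, and
broadleaf weed. Grass and broadleaf weeds respond to different
herbicides, so the two weed forms must be separated per pixel. The
pipeline has three stages with distinct responsibilities:

* the **vegetation stage** separates plant matter from background using
  only color (excess-green index + Otsu threshold) — no learning;
* the **network** separates soybean from grass weed (and background)
  using learned shape/texture features — grass blades are narrow and
  elongated, soybean leaflets broad;
* the **morphological stage** recovers broadleaf weeds as the
  vegetation that the network attributed to neither soybean nor grass.

This division means the network solves a 3-class problem and never
needs broadleaf annotations; broadleaf is deliberately unlabeled.

## Model

**Encoder.** ResNet34 (stem 7×7/2 + stages of 3/4/6/3 basic blocks at
64/128/256/512 channels) with a squeeze-and-excitation module in every
basic block. SE squeezes each channel of the residual-branch output by
global average pooling, passes the C-vector through a two-layer
bottleneck (reduction r, ReLU, then sigmoid), and rescales each channel
by the resulting weight in (0,1). SE sits on the residual branch before
the shortcut addition, so an SE block with all weights pinned to 1
degenerates exactly to a plain residual block (tested). Defaults:
r = 16, SE in every block; both are configurable, and `use_se=False`
gives the plain-ResNet34 ablation. The five encoder taps are the
outputs at scales 1/2 (post-stem), 1/4 (stage 1), 1/8, 1/16, 1/32 with
channels 64, 64, 128, 256, 512 — the first five downsampling results.

**Decoder.** Classic UNet: four 2×2 stride-2 transposed-convolution
upsamplings with decoder widths 512→256→128→64→64, each concatenated
with the same-resolution encoder tap and refined by two 3×3 conv-BN-ReLU
layers, then a fifth upsampling (no tap exists at full resolution) to
the input size.

**Shallow-feature fusion.** Each of the five taps is compressed to 16
channels by a 1×1 convolution and restored to full resolution by a
chain of log2(scale) 2×2 stride-2 transposed convolutions (1…5 steps).
The five restored maps (80 channels) are concatenated with the decoder
output and a final 1×1 convolution produces the 3-class logits. Two
deliberate choices here:

* *Compression before restoration.* Restoring a 512-channel map through
  five deconvolution levels before compressing would dominate the whole
  network's compute; compressing first is the same family of linear map
  at a fraction of the cost, and the fused channel width (16 per tap) is
  the free parameter either way.
* *Fusion point.* The restored taps join after the decoder reaches full
  resolution, immediately before classification, so the fusion structure
  is strictly additive: `enable_fusion=False` recovers the plain
  ResNet34-UNet wiring unchanged (parameter counts are strictly ordered
  across the four ablation configurations, which the tests assert).

**Prediction.** Class = per-pixel argmax of the raw logits (softmax is
monotone, so it is applied only inside the loss); ties break to the
lowest class index.

## Training regime

Per-pixel cross-entropy over 3 classes, Adam with β₁ = 0.9
(β₂ = 0.999), batch size 8, 500 epochs. The learning rate follows a
cosine from 0.01 (epoch 1) down to 0.001 (final epoch) — the schedule
only needs to be monotone with those endpoints, and cosine is the
standard smooth choice. The first 50 epochs freeze the encoder: its
parameters and batch-norm statistics are bit-identical across frozen
steps (the encoder is kept in eval mode), and only decoder/fusion/head
parameters update. At the unfreeze boundary a fresh Adam optimizer is
created over all parameters, since the parameter set changes and stale
moments for never-trained weights would be meaningless.

After the last epoch a batch-norm recalibration pass replaces the
running statistics with the exact activation statistics of the final
weights (cumulative-average momentum 1/t over one sweep of the training
data). Without it, eval-mode inference after short runs reflects
statistics gathered while the weights were still moving.

Validation mIoU is computed per epoch when a validation set is given,
and the best-scoring state is restored at the end.

## Numpy network layer

No deep-learning framework is used; `weedseg.nn` is a tape-based
reverse-mode autodiff engine over numpy arrays. Convolution is lowered
to BLAS matrix products via im2col (a 9-slice loop for 3×3 kernels);
transposed convolution is restricted to kernel = stride (the only case
the architecture uses), where each input pixel paints a disjoint output
patch and forward/backward are single einsums. All arithmetic is
float32. After `backward()` the tape's closure cycles are broken
explicitly so large intermediate buffers free by reference counting —
peak training memory stays ≈1 GB for the 24.6 M-parameter full model at
batch 8 on 64×64 inputs. Numerical gradients of every operator were
verified against central differences during development.

## Vegetation stage

ExG = 2G − R − B is computed on raw 0–255 channels and clamped to
[0, 255]; chromaticity normalization is unnecessary because the Otsu
threshold adapts to the histogram scale. Otsu maximizes the
between-class variance ω₀ω₁(μ₀−μ₁)² over all 256 thresholds (class 0 is
v ≤ t); ties break to the lowest maximizing threshold, and constant
images are rejected as having no separable classes. Binarization is
strict (> t).

## Metrics

mIoU = mean over the 3 annotated classes of TP/(TP+FP+FN);
mPA = mean per-class recall TP/(TP+FN), both from an exact K×K pixel
confusion matrix. A class absent from both prediction and truth has an
empty union; it scores 1.0 by convention (dropping it from the mean
instead is available via `include_absent=False`). Both metrics are
invariant under simultaneous relabeling of prediction and truth, which
the property tests exercise; no ordering between mIoU and mPA is
asserted because none holds in general.

## Broadleaf extraction

`broadleaf = vegetation ∧ ¬(soybean_pred ∨ dilate(grass_pred))`,
followed by 8-connected component area filtering and composition into
the four-class map with overlap priority grass > soybean > broadleaf.
Defaults: 5×5 square structuring element, one dilation iteration,
min_area 64 px at 512×512 — all exposed as parameters since no
reference values exist. Grass is dilated (thin blades fringe into
neighboring vegetation pixels); soybean is not. "Adding" masks is
implemented as boolean set algebra, which coincides with saturating
addition on binary inputs.

## Synthetic scenes

The generator stands in for field acquisition: brownish soil
(RGB ≈ (120, 90, 60)) with Gaussian texture noise (σ = 12) and a few
gray stone ellipses; soybean as 2–3 broad elliptical leaflets fanned
around a node; grass as tapered curved blades with enforced elongation
(measured major/minor axis ratio ≥ 5); broadleaf as single large
rounded ellipses. Plant greens are drawn from G ∈ [130, 210] against
soil green 90, keeping the excess-green margin decisively positive —
these are the study conditions, fixed once. Overlaps resolve by the
priority grass > soybean > broadleaf, mirroring the composition rule.
Placement commits transactionally: a plant that lands fewer than 12
visible pixels is retried, so no stub fragments contaminate ground
truth. `plant_scale` decouples plant size from scene size; dense 64×64
fixtures use plant_scale 0.5 so plants cover ≈20 % of the frame, which
keeps "predict everything background" well below the accuracy bar of
the learning-capability check.

What the generator does *not* model: lighting and shadows, perspective,
leaf venation, growth stages, plant occlusion geometry beyond flat
painting. Passing tests therefore demonstrate pipeline correctness and
learnability of shape/color cues, not field-scale accuracy; headline
field numbers require real imagery and are out of scope.

## Problem sizes

Desk-scale runs use: 700 source scenes at 64×64 for the expansion/split
arithmetic; 8 dense 64×64 scenes for the overfit capability run
(capped at 150 epochs, early-stopped once training pixel accuracy
exceeds 0.97, typically ≈25 epochs); 512×512 single-image forwards for
the architecture contract; 100 random images/masks per oracle-
equivalence suite. The 500-epoch field protocol remains the default of
`TrainConfig`/`WeedSegmenter` and is exercised end-to-end by the same
code path at the reduced sizes.

## Known limitations

* Transposed convolutions require kernel = stride; arbitrary
  configurations are not implemented (not needed by this architecture).
* `ConvTranspose2d` chains in the fusion branch are learned upsamplers
  initialized randomly; with very short training they can pass through
  checkerboard artifacts typical of deconvolution stacks.
* The train loop holds the dataset in memory; it targets hundreds to a
  few thousand small images, not streaming corpora.
* Loading externally pretrained ResNet34 weights is not implemented;
  the freeze phase still functions (it fine-tunes the decoder against a
  fixed random encoder), but its transfer-learning benefit presumes a
  pretrained backbone.
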