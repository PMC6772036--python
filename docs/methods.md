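# Methods

`whaledetect` implements a semi-automated, tile-based whale-detection
pipeline for very high-resolution ocean imagery: a two-class (whale vs
water) image classifier is trained on down-sampled aerial-resolution tiles
and applied, without further refinement, to satellite-resolution tiles. The
package reproduces the full workflow — data-preparation geometry,
imbalance-aware training, classical baselines, and the evaluation
conventions — and ships a synthetic scene generator so every stage is
testable without proprietary aerial footage or commercial satellite scenes.

## The survey model

A survey pairs two sensors observing the same kind of ocean:

* **aerial**: ~2 cm ground-sample distance (GSD), the source of labeled
  training data. Aerial frames often capture the same individual repeatedly
  ("duplicate frames"), which enriches training but can leak information
  across naive splits.
* **satellite**: 31 cm GSD panchromatic with 124 cm multispectral (MS)
  bands, the deployment target. MS bands are Gram-Schmidt pansharpened with
  the pan band, and only the red/green/blue bands are kept, approximating
  the aerial RGB modality.

Aerial scenes are bilinearly down-sampled to the satellite GSD
(output dimension = round(dim x src_gsd / target_gsd)), every scene is cut
into 32 x 32 px tiles (98.4 m^2 at 31 cm), and each tile is labeled whale or
water. Tiles are enlarged (default bilinear) to the classifier's input size
when the backbone requires it.

### The 20% retention rule

A whale bisected by a tile border produces sliver tiles that even a human
can only interpret in context. A tile counts as a whale tile when at least
20% of a whale's total mask pixels fall inside it (boundary inclusive); a
tile with a positive fraction below 20% is excluded from *both* classes.
The fraction's denominator is the whale's total pixel count, not the tile
area (a tile-coverage variant is deliberately not the default). After
down-sampling, masks are carried as fractional-coverage rasters (exact
area-weighted averaging) so the rule stays meaningful at 31 cm.

## Synthetic scenes

The generator emulates the *structure* of the survey data, not ocean
radiometry:

* **Water** is a blue-green base colour plus directional low-frequency wave
  streaks and a Bernoulli whitecap speckle whose rate grows with an ordinal
  `sea_state` (0 = flat calm … 5 = heavy whitecaps). Texture is generated on
  a fixed 0.31 m metric process grid and resampled to the sensor GSD, so a
  2 cm aerial scene and a 31 cm satellite scene of the same sea state share
  ocean statistics — the property that makes aerial-to-satellite transfer
  possible at all. Whitecap fraction is non-decreasing in sea state by
  construction (tested).
* **Whales** are anti-aliased elongated shapes (a 5:1 body ellipse plus a
  tangent fluke lobe, overall major axis exactly `length_m / gsd_m` pixels),
  darker than local water by a configurable `contrast` margin (default
  0.15 reflectance units) with mild per-pixel jitter. Default lengths are
  7–9 m ("minke-like") for aerial training scenes and 12–16 m
  ("right/humpback-like") for satellite test scenes; these are generator
  knobs, not biological claims. Each individual can appear in several
  duplicate frames with jittered pose/position, sharing `individual_id`.
* **Distractors** (bright elongated boats, dark detritus patches) carry no
  instance record.
* Optionally a scene carries an MS/pan pair: pan is the fine-grid luminance;
  the MS stack is the 4x block-average of (blue, green, red, NIR) with NIR
  modelled as attenuated luminance (water absorbs NIR).

Determinism: identical parameters (including seed) give bit-identical
rasters and masks.

What the generator does **not** emulate: sensor noise models, sun glint,
clouds, radiometric calibration, turbidity gradients, or realistic whale
photometry. Passing tests therefore demonstrate that the pipeline machinery
is correct and that the method's qualitative behaviour (imbalance handling,
transfer across GSD, degradation with sea state and contrast) is
reproduced — not that any particular accuracy will be achieved on real
imagery.

## Gram-Schmidt pansharpening

Implemented in the standard gain/injection form, equivalent to
orthogonalising the band vectors against a simulated low-resolution pan and
substituting the true pan before inverting:

1. `pan_sim = Σ w_b · ms_b` (weights default uniform, normalised);
2. per-band gain `g_b = cov(ms_b, pan_sim) / var(pan_sim)`;
3. the true pan is affinely matched so that its *degraded* (block-averaged)
   version has the mean/std of `pan_sim` — matching at the coarse scale is
   what makes the fused product block-average back to the input MS;
4. `fused_b = up(ms_b) + g_b · (pan_matched − up(pan_sim))` with
   block-replicate upsampling, clipped to [0, 1].

Degenerate contracts hold exactly: if the pan equals the upsampled simulated
pan the output is the upsampled MS; if all MS bands equal the block-averaged
pan the output is the pan replicated per band. Spectral consistency
(block-average of the fused product vs input MS) is enforced at RMSE < 0.02
across all sea states; with the scene model above it is ~3e-4.

## Classifier

The harness trains a two-logit head with softmax cross-entropy, SGD with
momentum 0.9, and a step-decay schedule: lr(e) = base · decay^floor((e−1)/7)
with decay 0.1 (the decay factor is not fixed by the protocol this package
follows; 0.1 is the conventional step-decay value and is configurable).
Class imbalance is handled by a weighted random sampler: each tile's weight
is the inverse of its class count, so with replacement-sampling the expected
whale share of any batch is 1/2. Every epoch ends with a checkpoint and a
held-out evaluation; `select_best_epoch` picks the argmax-F1 epoch (ties to
the earliest).

The shipped backbone is `smallnet`: three 3x3-conv/ReLU/2x2-max-pool blocks
(8, 16, 32 channels) and a 64-unit dense layer, implemented in numpy with
analytic gradients (verified against finite differences). It trains from
scratch on one CPU in minutes at 32 px inputs. The torchvision family names
(`resnet18/34/152`, `densenet`) are accepted in `TrainConfig` for
configuration compatibility but require the optional torch backend and raise
an explicit error in this build, as does `pretrained=True` (smallnet has no
pretrained weights; there is no silent random-init fallback).

Numerical/decision conventions: inputs are normalised with per-dataset
channel statistics; the hard-label threshold is p_whale > 0.5 with ties to
water (a degenerate untrained model then floods nothing into the review
queue); a non-finite loss aborts with a diagnostic; `learning_rate = 0` is
legal and freezes the dynamics (useful as a control). One master seed fans
out to init and sampling; runs are bit-reproducible on a platform, up to
BLAS reduction-order caveats across platforms.

Default hyperparameters mirror the reference protocol (base LR 0.0006, step
7, momentum 0.9, 24 epochs, batches 4–32, 224 px inputs) — values tuned for
fine-tuning a pretrained deep backbone. The shipped quickstart overrides
base LR to 0.01 and inputs to 32 px, the conventional regime for a compact
net trained from scratch.

## Baselines

Histogram-of-oriented-gradients features (8 px cells, 2x2 blocks, 9 unsigned
bins, L2-Hys; the canonical detector configuration, config-exposed) feed a
ridge classifier (one-hot regression with L2 penalty α = 1, argmax with
ties to water) and a C-SVC (C = 1, RBF kernel with scale-heuristic
bandwidth; linear selectable). Baselines train on a balanced subset (all
whale tiles plus an equal number of random water tiles) of native 32 px
tiles — interpolation to 224 px adds no gradient information — and are
evaluated through the identical dataset and metrics path as the CNN.

## Evaluation conventions

Precision/recall/F1 are computed with **water as the positive class**:
precision = share of model-classified water that is truly water, recall =
share of true water found. The **whale-detection false-positive rate** —
water tiles flagged as whale, i.e. reviewer burden — is a separate
convention reported side by side (87 of 1,390 gives 6.26%). Undefined
metrics (zero denominators, e.g. an all-whale fold with nothing predicted
water) surface as explicit "undefined" markers, never silently as 0 or NaN.
Reports round to 3 decimals; CSVs keep full precision.

Splits are stratified: 90/10 via 10 folds by default, with per-fold class
counts differing by at most one when the split unit is the frame. The
`individual` unit instead keeps all duplicate frames of one whale in a
single fold (preventing duplicate-frame leakage) at the cost of slightly
less even counts; `frame` remains the default to mirror the reference
protocol's arithmetic.

## Problem sizes in shipped recipes

The quickstart recipe is desk-scale by design: 10 aerial scenes of 2480 px
at 2 cm (49.6 m square; a 5x5 tile grid after down-sampling, ~250 aerial
tiles with ~4:1 to 8:1 water:whale imbalance) and 4 satellite scenes of
320 px at 31 cm (~390 test tiles). The hard condition is contrast 0.05 with
sea_state 3. These sizes exercise every stage — including genuine class
imbalance and the aerial-to-satellite transfer — while keeping a full run
to about a minute on one CPU; the tens-of-thousands-of-tiles regime of a
real survey is reached by scaling the same configuration up.

## Known limitations

* Water-positive F1 is insensitive at strong imbalance (a predict-all-water
  model already scores high); the whale-detection FPR and the triage list
  are the operationally meaningful outputs.
* The per-tile retention rule cannot guarantee that a whale fragmented
  across many tiles (every fragment < 20%) surfaces as a whale tile
  somewhere; with 7–16 m whales on a 32-tile grid at 31 cm this requires an
  unlucky four-way split and does not occur in practice.
* `smallnet` is not a substitute benchmark for deep pretrained backbones;
  comparisons between backbone families require the optional torch backend.
* The generator's contrast default is a placeholder for unknown real
  whale/water contrast statistics; it sets test hardness and makes no
  fidelity claim.
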