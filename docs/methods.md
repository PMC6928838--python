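# Methods

## Problem setting and model

A drone survey produces nadir RGB frames at roughly 30 m altitude, giving a
ground sampling distance (GSD) of 0.0131 m/px. Frames are divided into a
regular grid of square patches (default 200×200 px); the patch is the unit of
classification, ground-area accounting and map display. Partial strips at
the right/bottom edges are discarded rather than padded, so every counted
patch represents a full (GSD·tile)² footprint — 6.86 m² at the default
profile — and all published-style area accounting is `count × 6.86` with
2-decimal rounding. The unrounded footprint (6.8644 m²) is available through
the `rounding` parameter of `tile_footprint_area`.

Each patch receives one of eight classes: a health component — healthy (H),
dry (D), unhealthy (UNH), no vegetation (NV) — crossed with a binary
contamination flag (suffix C). Biomass percentage is defined as the share of
patches whose class has a vegetation component, **including** contaminated
variants (H, D, UNH, HC, DC, UNHC); this definition reproduces the reference
surveys' published biomass figures (67.76 / 9.37 / 78.69) exactly from their
label counts. Contamination percentage is the share of the four C-classes.
Vegetated and non-vegetated classes partition the grid, so
`biomass% + (NV+NVC)%  = 100` identically. One reference survey (ESCOM-IPN)
publishes a biomass figure (47.34) that does not follow from its own label
counts (which give 49.44), and the published contamination column is not
derivable from the counts under this (or any simple) ratio; those figures
come from model predictions over full maps that are not published, so they
are documented here and not used as checks.

### Georeferencing

Tile centers are georeferenced under a local north-up equirectangular
approximation: pixel offsets from the frame center scale by the GSD to
east/north metres, then 1° latitude = 111,320 m and longitude is scaled by
cos(latitude). Over a single frame (hundreds of metres at most) the
approximation error is far below the GSD. Heading is assumed north-up;
orthomosaic stitching, lens correction and projected CRS transforms are out
of scope. EXIF GPS is read when present and never required — the whole
pipeline operates in plain grid coordinates otherwise.

## The classifier

A compact CNN+MLP implemented directly on numpy (im2col convolutions,
vectorised max-pooling, Adam, softmax cross-entropy):

- three blocks of 3×3 valid convolution (32, 64, 128 filters) + ReLU +
  2×2 max-pool;
- flatten → fully-connected 128 ReLU → fully-connected 8 with identity
  (linear) output transfer; probabilities are the softmax of the logits,
  applied at prediction time and folded into the loss during training.

The layer sizes are a documented default, overridable through
`TrainingConfig(conv_filters=…, hidden_units=…)`. Inputs are scaled to
[0, 1]; no augmentation, no regularisation, no early stopping, no class
reweighting by default (reweighting is available as a config flag because
contaminated classes are rare in realistic label distributions).

The shipped default profile is batch size 20, 200 epochs, Adam at 1e-2,
ReLU, cross-entropy. Two readings of "200 iterations" are supported: epochs
(default) and a literal `max_steps` cap on optimiser steps. Adam at 1e-2 is
frequently unstable for convolutional nets, so the validation benchmark uses
1e-3 with 25 epochs — a robust profile on the synthetic scenes — while the
defaults remain the fidelity profile.

Everything is deterministic for a given seed: initialisation (He-normal from
a seeded generator), batch shuffling, and therefore the trained parameters;
two runs with identical inputs are bit-identical. `retrain` warm-starts from
the current parameters with a fresh optimiser state, which models the
load-new-terrain-and-retrain workflow.

## Synthetic scenes

The generator is the package's stand-in for real flights and defines the
conditions under which the pipeline is validated:

- per-health-state textures built from band-limited correlated noise
  (uniform noise smoothed at two spatial scales plus a per-tile colour
  jitter): green-dominant for healthy, yellow/brown for dry, a soft-edged
  blob mixture of green and brown for unhealthy (deliberately overlapping
  the healthy and dry colour statistics, mirroring the confusion structure
  real classifiers show), and low-saturation gray for no-vegetation;
- contaminated variants overlay 3–10 small convex high-contrast polygons
  ("litter": white, red, blue, yellow), each under 5% of the tile and
  jointly under 25% of pixels (a running coverage cap guarantees the bound);
  the underlying texture is bit-identical to the clean twin at the same
  seed, so contamination is a strictly local signal;
- one master seed per scene with per-cell seeds derived through
  `SeedSequence(master, row, col)`, making scenes reproducible under partial
  regeneration and making scene tiling bit-identical to direct per-cell
  synthesis.

The textures are calibrated to be separable but not trivial: a
nearest-centroid classifier on mean RGB reaches ≈75% (the guaranteed floor
in the tests is 70%), with the residual confusion concentrated in
clean-vs-contaminated pairs at low litter coverage and in the unhealthy
class. What passing tests on these scenes shows is that the pipeline —
tiling, loading, optimisation, prediction, accounting — is correct and that
the network can exploit local colour/texture signal; it does **not** show
that real-world accuracies (which sit near 70% on hand-labelled imagery with
mixed-content patches, shadows and seasonal variation) are reproduced.
Photorealism, flight geometry, shadows and label noise are explicitly not
modelled.

## Validation benchmark and problem sizes

`greenmap.validation.classifier_benchmark` runs the end-to-end experiment:
train on a balanced terrain of 640 patches (80 per class), test on a
seed-disjoint balanced 160; predict a 16×16 scene drawn with a reference
survey's empirical class imbalance and compare map-level biomass against the
planted truth; then warm-start retrain on a second terrain (600 training /
120 test patches, a different class mix) and measure the accuracy drop.
Patches are 32×32 px here — the texture statistics are scale-free, and this
size lets the numpy network train in about a minute on one CPU; held-out
accuracy is ≈99%, map biomass error 0 percentage points, and the retraining
drop under 1 point at the benchmark profile.

## Numerical choices and edge cases

- Argmax ties in prediction resolve to the lowest class index in the
  canonical order (H, D, UNH, NV, HC, DC, UNHC, NVC).
- Metrics on empty matrices or zero denominators raise errors rather than
  returning silent zeros, so degenerate evaluations surface in tests.
- Percentages and areas are rounded to 2 dp at the reporting boundary only;
  internal arithmetic is exact.
- Dataset splits are stratified by class whenever every class has at least
  two records and the test draw can represent each class (plain random
  otherwise): rare contaminated classes would otherwise vanish from small
  test draws.
- The learning rate may be exactly 0 (a no-op update), which makes
  "retrain with nothing to learn" a well-defined identity operation.
- Softmax is computed with max-subtraction; cross-entropy clamps
  probabilities at 1e-12. A non-finite training loss aborts with an error
  naming the epoch.

## Known limitations

- The local equirectangular georeference degrades near the poles and for
  non-north-up imagery.
- The numpy network is CPU-bound; at the production 200 px patch size,
  training on tens of thousands of patches is slow — the design target is
  correctness, reproducibility and portability, not throughput.
- Mixed-content patches (half grass, half pavement) carry a single label;
  no majority-area rule or label-noise model is applied.
- Duplicate ground coverage from overlapping frames is not deduplicated;
  every source frame is treated independently.
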