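# Methods

`mtsimg` classifies multivariate time series (MTS) by turning each sensor
channel into a coloured 2-D field image, concatenating the per-channel
images into one RGB tensor, and training a convolutional network. This note
records the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic benchmark does and does not establish.

## Encoding model

Each channel `x(1..T)` is processed independently:

1. **Rescale** to `[0, 1]` by `(x - min) / (max - min)`. A constant channel
   has no scale; it maps to all 0.5 so one flat sensor does not abort a
   batch (MTF on such a channel still raises a degenerate-binning error,
   since a single distinct value admits no quantile bins).
2. **Length normalisation** to the image size `n`. Reduction uses piecewise
   aggregate approximation (PAA): contiguous segments with 1-based
   boundaries `floor(l*T/N)`, sizes differing by at most one, each replaced
   by its mean. This integer-boundary rule is deterministic and coincides
   with the fractional definition whenever `N` divides `T`. If `T < n`
   (rare; lengths below the image size), the series is linearly
   interpolated onto `n` equally spaced points, which preserves shape
   without inventing structure.
3. **Field encoding**, one of:
   - **GASF** `cos(phi_i + phi_j)`, `phi = arccos(x)`, computed in the
     algebraic form `x x' - sqrt(1-x^2) sqrt(1-x^2)'`. Symmetric; the
     diagonal `2 x_i^2 - 1` makes the rescaled series recoverable as
     `x = sqrt((diag + 1) / 2)`.
   - **GADF** `sin(phi_i - phi_j) = sqrt(1-x_i^2) x_j - x_i sqrt(1-x_j^2)`.
     Antisymmetric, zero diagonal. (The summation-field form of the sine
     matrix is internally inconsistent with the algebraic outer-product
     form; the difference form is the one implemented.)
   - **MTF** `W[bin(x_i), bin(x_j)]` where `W` is the row-stochastic
     first-order transition matrix between quantile bins estimated from the
     series' own consecutive pairs. Bins are right-closed with the lowest
     bin closed on both ends; values equal to an edge fall in the lower
     bin. Default bin count **b = 8**: a power-of-two count that keeps at
     least a handful of samples per bin at image sizes of 32-128.

   Inputs are clipped to `[0, 1]` within 1e-12 before `arccos`/`sqrt` to
   absorb floating-point rounding; anything further outside is an error.

## Colour and concatenation

Fields are rendered through a fixed five-anchor piecewise-linear rainbow
(`0 -> blue, 0.25 -> cyan, 0.5 -> green, 0.75 -> yellow, 1 -> red`), scaled
by each encoder's *theoretical* range (`[-1, 1]` Gramian, `[0, 1]` MTF)
rather than the per-image min/max, so colour carries the same meaning in
every image. "Rainbow, red = high, blue = low" admits many realisations;
the anchors are pinned so the extremes are pure blue/red and the midpoint is
green.

Each per-channel colour image is split into its R/G/B planes and
like-coloured planes are stacked vertically in a chosen channel order,
giving a `3 x (n*m) x n` tensor for `m` sensors. The network therefore
always sees three input channels; the concatenation order only moves the
`n`-row blocks (and hence the "spurious edges" between them), which is
exactly the degree of freedom the order-comparison experiment probes.

## Classifiers

Two architectures, both with ReLU after every hidden layer, same-padded
convolutions (so pooling alone halves the spatial dims — the `/2^k`
arithmetic is exact and enforced up front), softmax two-class output:

- **simple**: two 5x5 conv layers with (6, 12) filters, each followed by a
  2x2/stride-2 max pool, then one fully-connected output layer. Default
  learning rate 0.0023.
- **vgg16**: the canonical 13-conv (3x3) / 5-pool / 3-FC stack with filter
  counts (64..512) and FC sizes (4096, 4096, 2). Default learning rate
  0.00023. Its parameter count exceeds the simple net's by far more than
  100x at any supported input size.

Filter counts, optimiser and loss are the package's own choices where the
family definitions leave them open: SGD with momentum 0.9, batch size 16,
two-class cross-entropy, He initialisation. Training holds out a stratified
`validation_fraction` (default 0.1) split, stops once validation loss has
not improved for `patience` (default 10) epochs or at `max_epochs` (default
200), and restores the best-validation weights. All randomness
(initialisation, shuffling, splits) flows through one integer seed; a rerun
with the same seed, data and thread/precision settings reproduces the same
weights and predictions. Ties in the output argmax resolve to class 0.

The network itself is a compact numpy implementation (im2col convolution,
reshaping max-pool, dense layers) — deliberately small, CPU-only and
dependency-light, sized for the input shapes this package produces.

## Evaluation protocol

`run_condition` encodes the dataset once per condition, then runs
`repeats x` stratified 5-fold cross-validation (stratification prevents
single-class training folds on small datasets; plain k-fold would not
guarantee that). Seed lineage: repeat `r` splits with `base_seed + r` and
trains fold `f` with `base_seed + 97 r + f`, so every model in a run is
replayable from one base seed. Error rate is `(1 - correct/N) * 100` on the
held-out fold.

Comparisons:

- **Encoders** — Dunn post-hoc pairwise tests (tie-corrected rank z, normal
  two-sided p), reported raw and Holm-adjusted since the adjustment
  convention is a user choice.
- **Concatenation orders** — pairwise Wilcoxon signed-rank tests on errors
  paired by (repeat, fold). When two orders produce identical errors
  everywhere there are no signed ranks; the pair is reported as p = 1 with
  a `degenerate` flag rather than an error.
- **Architectures** — Kruskal-Wallis H across groups; all-identical data
  short-circuits to H = 0, p = 1 (scipy raises in that case).

The sample unit for the unpaired tests is the **per-repeat mean error over
folds** (one value per repetition of the CV); per-fold granularity is
available via `unit="fold"`.

## Synthetic benchmark

`generate_synthetic` emulates a six-sensor wafer-style binary benchmark:
per-instance lengths uniform on 104-198 (equal across channels within an
instance, varying between instances), each channel a random-phase 1-3 cycle
sinusoid of amplitude ~1 plus Gaussian noise (sd 0.1). Abnormal instances
are shifted down by `level_shift` (default 1) and receive `n_spikes`
(default 2) short triangular spikes of height `spike_amplitude` (default 2)
at positions shared across channels — a process event seen by every sensor.
Class balance is exact (`round(n * class_balance)` abnormal labels,
permuted). Increasing `spike_amplitude` monotonically increases the
difference of class-mean channel maxima, giving a controlled difficulty
dial.

**What it does not emulate.** Real sensor data has autocorrelated noise,
drift, channel cross-correlation structure, and class signatures far richer
than "shift + spikes". Passing the end-to-end checks here shows the
pipeline is wired correctly and can learn a genuinely present signature at
small sample sizes — not that any particular error rate carries over to
real benchmarks.

**The fixture is not encoder-neutral.** Quantile binning adapts to each
series' own distribution, so MTF is invariant to the per-series rescale and
almost invariant to spike *amplitude*; only the temporal pattern of the
spike survives, and at reduced image sizes (16-32) a spike occupies ~1
pixel. GASF/GADF, which keep amplitude geometry, separate the classes
easily (~1-3% error) while MTF retains little signal here (~30-47% error
depending on the seed).
This is a property of the fixture and encoder, not a defect: conclusions
about *relative* encoder quality on this fixture should not be generalised.

## Reduced problem sizes

The repeated-CV analyses run at deliberately small scale, chosen as the
package's default study conditions for a single CPU:

- learning sanity runs: 120 instances, m = 3, image size 32, 1 repeat x 5
  folds, `max_epochs 25 / patience 4`;
- encoder comparison: 100 instances, image size 16, 3 repeats x 5 folds;
- order comparison: 10 replications of 60 instances, image size 16,
  2 repeats x 5 folds, `max_epochs 15 / patience 3`.

Full-scale settings (image size 128, 20 repeats, VGG16) are supported by
the same code paths; VGG16 training is exercised in the test suite only at
tiny input sizes because training it at full resolution is not a CI-scale
computation in a numpy implementation.

## Known limitations

- MTF needs at least `b` distinct values per channel; heavily quantised or
  constant channels raise degenerate-binning errors instead of producing
  misleading fields.
- The Wilcoxon comparison requires identical (repeats, folds) layouts; it
  pairs by position, so results must come from the same base seed to be a
  paired design.
- Bit-exact training determinism assumes a fixed BLAS/thread configuration;
  across different numpy builds results may differ at floating-point level.
- PNG export quantises to 8 bits per channel (max round-trip error 1/510);
  the in-memory pipeline is float and does not pass through files.
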