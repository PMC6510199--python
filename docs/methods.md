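# Methods

This note records the models, parameters and numerical choices behind
`sinoup`, and what the synthetic experiments do and do not demonstrate.

## Sinogram model and array conventions

A tomogram is a 3-D array holding the same pixels in two layouts:
projections `(angle, height, width)` or sinograms `(height, angle, width)`.
All indexing is 0-based and half-open.  Projection row `t` of `T` sits at
angle `t·180°/(T−1)`, so the first and last rows are the 0°/180° pair; a
sinogram's θ axis therefore spans the closed sweep, and the row at 180° is
the left-right mirror of the row at 0°.  Sinogram values are treated as
given (attenuation line integrals for the synthetic data); the toolkit
never assumes a transmission-vs-log convention for real files.

## Patch geometry

Training pairs are cut from a fully sampled sinogram by sliding a window
of height `gap·(m−1)+1` with stride 1, where `m = 11` input rows sit at
multiples of `gap` inside the window.  For an upscaling factor `f`, the
ground truth has `N_out = f−1` channels; channel `c` holds the rows at
sub-offset `(c+1)·gap/f` of every inter-input gap, which requires
`gap % f == 0`.  The defaults `gap=40, m=11` reproduce the full-scale
regime: 401-row windows, inputs 0, 40, …, 400, 2×-targets 20, 60, …, 380.

Window starts run over `0 … T−402` — count `T−401`, i.e. 3200 for
T = 3601 — although one more full window would fit.  The convention
matches the published patch count and keeps the final row (the 180°
duplicate of row 0) from ever starting a window.

At inference the undersampled sinogram (L rows) is tiled into `L−10`
overlapping 11-row windows.  Each predicted gap pixel is averaged over
every window that covers it (up to 10; fewer at the edges — no synthetic
padding windows are introduced).  Interlacing the merged intermediate rows
with the input rows yields `f·(L−1)+1` rows with the inputs passed through
verbatim, so downsampling the output by `f` returns the input bit-exactly.

## Network

Three convolutional layers separated by two ReLUs; kernels 10×17, 7×13,
7×13 with 64/32 feature maps in the base model and zero padding (4,8),
(3,6), (3,6), so every feature map already has the output size (height
`m−1`, preserved width).  The last layer carries no ReLU: it linearly
combines feature maps into the `N_out` output channels.  Named variants:
`udnn128` (128/64), `udnn32` (32/16), `udnn-lk` (12×19, 9×15, 9×15;
paddings re-solved to (5,9), (4,7), (4,7)), `udnn-sk` (8×15, 5×11, 5×11;
(3,7), (2,5), (2,5)).  The network is fully convolutional, so inference
accepts any height ≥ 11.

Convolutions are cross-correlations (equivalent up to a kernel flip the
optimizer absorbs) evaluated in the frequency domain: real FFTs of the
padded input and the flipped kernels, a batched complex matrix product
contracting the channel axis, and an inverse FFT.  Wide inputs are
processed in overlap-save blocks of ~384 detector columns so the kernel
FFTs stay small and are reused.  Gradients are the standard conv-layer
adjoints, also computed via FFT.  All tensors are float32; the forward
pass agrees with a dense float64 convolution composition to ~1e-7 relative.

Weights are He-initialized (N(0, 2/fan_in), biases zero, seeded).  With
the ReLU layers and the all-positive normalized inputs, variance-preserving
initialization keeps early gradients informative; a fixed tiny kernel scale
(the classical super-resolution convention) measurably stalls Adam for
hundreds of steps at these learning rates, so it is not used.

## Training

Loss: mean square error over the pixels of the predicted intermediate
rows.  Optimizer: Adam (β₁=0.9, β₂=0.999, ε=1e-8) with two learning-rate
groups — layers 1–2 starting at 0.01 and layer 3 at 0.001 (defaults of
`TrainSchedule`); biases share their layer's group.  One *iteration* draws
one uniformly random patch from every training sinogram in freshly
shuffled order; patches feed through in minibatches of 10 (final partial
batch kept).  Input patches are min–max normalized to [0, 1] per patch
(constant patches are flagged and map to zeros); targets are normalized
with their own input's parameters, and predictions are denormalized before
any comparison with raw ground truth.  Every 16 iterations the model is
validated on a frozen set of 10 seeded random patches per validation
sinogram; a snapshot is kept whenever the validation loss improves.  After
`patience = 3` validations without a new minimum both rates are divided
by 10; training stops after `max_decays = 3` decays or `max_iterations`,
returning the best snapshot.  The plateau rule is a deterministic,
testable stand-in for manual trend-watching.  A non-finite training loss
aborts with the offending state recorded in the history.

## Synthetic corrosion phantom

The generator emulates an in-situ corrosion experiment: an aluminium-like
pin (finite cylinder, density 1.0, radius 0.28 scene units), a salt-water
droplet on its top (half-ellipsoid, semi-axes (0.24, 0.24, 0.30), density
0.55), hydrogen bubbles rising in the droplet (spheres, radii uniform in
[0.03, 0.07], density −0.35 — negative because they displace droplet
material in the additive projector), and 40 magnesium-like deposits inside
the pin (ellipsoids, semi-axes uniform in [0.015, 0.045], density 0.5).
Three bubbles in the training scene, four in the testing scene; all
placements uniform in their admissible regions from a seeded generator.
Densities and ranges are configurable; the defaults were chosen once for
plausible attenuation contrast (line integrals ≲ 0.7) and are not fitted
to anything.

Projection is analytic: density × chord length per ray, with closed-form
quadric/ray intersection, clip planes for the cut droplet, and per-primitive
height culling.  The projector is exactly linear in densities and matches
adaptive-quadrature and bisection oracles to ~1e-8.  Poisson counting noise
uses incident flux I₀ = 10⁴ expected counts (giving noise σ ≈ 0.01 on line
integrals ~1, a visibly noisy but reconstructable regime); counts of zero
are clamped to one before the log.

What the phantom does *not* model: fly-scan blur, detector point spread,
flat/dark-field structure, ring artifacts, beam hardening, and the abrupt
temporal events (bubble pop-offs) of real corrosion sinograms.  Passing
the synthetic benchmarks therefore demonstrates the geometry, training
machinery and the denoising/interpolation advantage of the learned
upscaler — not performance on real beamline data.

## Desk-scale study conditions

The reference study (`sinoup.demo`, the CLI `demo`, the acceptance script)
runs at sizes one CPU trains in minutes while preserving the structure of
the full-scale experiment:

| quantity | desk scale | full scale |
|---|---|---|
| tomogram | 64 × 721 × 256 | 1080 × 3601 × 1280 |
| undersampling | 8× → 91 rows | 40× → 91 rows |
| patch gap / window | 8 / 81 rows | 40 / 401 rows |
| network | udnn128 features ÷ 4 → (32, 16) | (128, 64) |
| starting LRs | 1e-3 / 1e-4 | 1e-2 / 1e-3 |
| training length | 256 iterations (2×), 224 (4×) | plateau (~4 h GPU) |

Height split: even heights train, odd validate (alternation keeps both
halves representative of a sample whose structure varies with height);
every 10th height of the separate testing phantom is benchmarked.  The
learning rates sit one decade below the full-scale recipe because a
desk-scale minibatch covers ~100× fewer pixels, and the noisier gradients
make the full-scale rates non-descending; the decade ratio between the
two groups is preserved.

## Parameter-recovery check

The training machinery is validated on a task with a known generative
operator: sinograms exactly linear along θ per detector column, for which
every intermediate row is the mean of its two neighbouring input rows at
every window phase.  The check trains on one set of random ramps and
requires near-zero MSE on *unseen* ramps — recovery of the operator, not
memorization.  It uses a compact member of the architecture family
(8/4 feature maps, kernels 2×3, 3×3, 3×3; the first layer spans exactly
the neighbouring rows): the averaging operator is then a sparse exact
optimum that Adam reaches in a minutes-scale run, whereas with the
full-size kernels the approach to the exact optimum is too slow for a
desk-scale budget (the operator is still representable there — single
centre taps — but thousands of times more parameters must cancel).

## Evaluation

PSNR is `10·log₁₀(peak²/MSE)` with `peak` defaulting to the ground truth's
data range (the convention is configurable); identical images are flagged
infinite.  SSIM uses Gaussian-weighted 11×11 windows, σ = 1.5, population
covariances, K₁ = 0.01, K₂ = 0.03.  Sinogram-space scores use only the
predicted intermediate rows — rows copied from the input are excluded.
Reconstruction uses parallel-beam FBP (Ram-Lak filter, linear
backprojection); the region outside the inscribed circle is set to a NaN
sentinel, masked metrics exclude sentinel pixels, and comparisons happen
on a central crop (half the width by default), mirroring the windowed
comparison used when reconstructors emit masked borders.  This FBP is a
plain reference implementation: absolute reconstruction scores are not
comparable across reconstructors, so the experiments assert orderings and
trends, never absolute reconstruction values.

## Known limitations

- Training is CPU-bound NumPy; full-scale (128, 64)-feature training at
  width 2560 is out of reach here by design.
- The plateau-decay rule approximates, but cannot reproduce, a manually
  steered learning-rate schedule.
- The 4× model shares the 2× patch geometry (`gap % 4 == 0` required);
  factors whose sub-grid does not divide the gap are unsupported.
- Real-data conveniences (first-sinogram metadata skipping, configurable
  HDF5 dataset paths) are present, but no full NeXus-standard support.
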