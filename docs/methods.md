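# Methods

`wormseg` implements the analysis chain of a channel-device *C. elegans*
developmental-toxicity (DevTox) assay: semantic segmentation and occupancy
classification of worms immobilized in parallel microfluidic channels,
extraction of per-worm body endpoints (length, area, volume) and gut
autofluorescence, and dose–response statistics (EC10 with confidence
intervals, LOAEL, control CV). This note records the models, the defaults
and why, the numerical choices, and what the synthetic data generator does
and does not establish.

## Imaging model and geometry

A device has 24 wells with 40 gently tapering trapping channels each (960
channels), imaged as 5 fields of view (FOV) of 8 channels per well.  Each
FOV is a brightfield hyperstack of 5 time points × 10 z-slices at 6 µm
steps, plus a single fluorescence z-stack.  Channel crops are 5,056 px
tall; one 150 µm channel pitch spans ≈ 353 px, which fixes the default
pixel size at **0.425 µm/px** (a 4.25 µm camera pixel behind a 10×
objective; crop widths then fall in the documented 340–360 px range).
Every µm-valued output scales through this single constant.

Channel heights taper in discrete layers toward the exit (3 layers in the
adult "3L" device, 4 in the "4L" device that also traps L4 larvae).  The
layer boundaries/heights ship as YAML presets with **placeholder values**
(`src/wormseg/data/geometry_*.yaml`); they are device-calibration data and
must be calibrated before volumes are interpreted absolutely.  Relative
quantities (volume ratios, dose trends) are insensitive to the placeholder
scale.

## Preprocessing

* **Cropping.** Channel centerlines are predicted as
  `fiduciary_x + offset + k · pitch`, k = 0..7, rounded to the nearest
  pixel; each crop is one pitch wide.
* **Focus.** The best focal plane maximizes the variance of the
  4-neighbour discrete Laplacian of the slice; ties break to the lowest
  z index.
* **2.5D input.** The N slices on either side of the best plane are
  stacked as input channels — a (2N+1, H, W) tensor with N = 1 by default.
  Indices beyond the stack clamp by edge replication.  Width is padded
  symmetrically to 384 px (odd remainder → extra column on the right)
  using edge replication rather than zeros, so the network does not learn
  artificial boundary gradients as channel walls.  Intensities are
  min–max normalized to [0, 1] per crop; contrast augmentation covers
  residual variation.  Only the first time point is segmented (worms are
  immobilized; annotations use t = 0).

## Network

A 2.5D U-Net: a ResNet-style convolutional encoder (stride-2 learnable
downsampling, two 3×3 convolutions + group normalization + ReLU per block,
additive skip with 1×1 projection on channel change), a transformer
bottleneck, and a mirrored decoder (transposed-convolution upsampling,
skip concatenation) ending in 1×1 convolutions and a softmax over
{background, worm}.  At the bottleneck the (H/s × W/s) feature grid
(s = 2^layers, default 16) is projected to c = 256 channels, flattened
row-major into tokens, combined with learnable factorized positional
encodings (row table + column table, cropped to the grid so any input
size up to the configured maximum is accepted), and processed by a
4-layer pre-norm transformer (multi-head self-attention, 4× GELU
feed-forward, residual connections).  Long-range attention matters
because a worm spans thousands of pixels along the channel axis.  The
channel classifier pools the tokens with a single learnable seed vector
through cross-attention (pooling-by-multihead-attention) followed by
linear layers to 3 logits (full / partial / empty).

Unstated details resolved as: 8 attention heads (c = 256 → head dim 32);
group normalization (batch-size independent, deterministic) with a
`norm="none"` switch; strided convolution down / transposed convolution
up; 2 segmentation classes (annotation masks are binary).

**Numerical substrate.** The network runs on a small reverse-mode
autodiff engine written on numpy (`wormseg.nn`): conv2d / conv-transpose
primitives via im2col, matmul/reductions/normalizations with hand-written
vector-Jacobian products, AdamW.  Float32 by default; every primitive's
gradient is verified against central finite differences (in float64) in
the test suite.  CPU training is practical at reduced resolution (the
test configuration uses 2 encoder levels, c = 32 on 128×16 px crops,
≈ 0.3–0.9 s per batch-8 step); full-resolution 5,056 × 384 training is
supported by the same code but sized for GPU-class throughput, which this
implementation does not provide.

## Training

Base recipe: AdamW, initial learning rate 2·10⁻⁴, weight decay 10⁻²,
minibatch 32, cosine annealing with warm restarts (W₀ = 10, F = 2 — the
rate restarts at epochs 0, 10, 30, 70, 150, …) over 1,200 epochs, 8:1:1
class-stratified split (largest-remainder allocation with a
global-deficit tie-break keeps per-class proportions within one sample of
the global mix in every split).  Augmentation: horizontal/vertical flips,
rotations within ±5° (bilinear, edge fill; nearest-neighbour for masks),
gamma contrast in [0.7, 1.3].

Loss: `w_seg · L_seg + w_cls · L_cls` with w_seg = w_cls = 1.  `L_cls` is
3-way cross-entropy for every sample.  `L_seg` is soft-Dice plus pixel
cross-entropy, computed **only** for full-worm samples — only full worms
are annotated, so other samples contribute exactly zero and no gradient
reaches the decoder (asserted in tests).  Model selection keeps the
highest-validation-Dice checkpoint.

Few-shot fine-tuning to a shifted population (smaller, lower-contrast
worms in the 4-layer device): n new-domain samples mixed 1:1 with
original-domain samples to avoid catastrophic forgetting, 250 epochs of a
one-cycle cosine schedule.  The published peak rate of 10⁻⁶ is the
default but exposed (`TrainConfig.max_lr`): it is unusually small and may
be resolution- and scale-specific; the CPU-scale transfer experiments in
this package use 3·10⁻⁴, which reproduces the qualitative pattern
(shifted-domain Dice rises sharply, original-domain Dice drops by well
under 2 points).

## Post-processing and endpoints

* **Binarize** at 0.50 (a pixel exactly at 0.50 is foreground), after
  removing the padding columns.
* **Component filter**: keep the single largest 8-connected component if
  its area ≥ `min_area_px` (default 2,000 px ≈ 360 µm² at the default
  pixel size — far below any L4+ worm, above eggs/debris); everything
  else (eggs, debris, small larvae) is removed.  One worm per channel by
  chip design.
* **Length**: morphological thinning to a unit-width skeleton, then the
  longest geodesic path through the 8-neighbour skeleton graph (axial
  edges 1 px, diagonal √2 px).  Exact graph diameter is computed for
  skeletons up to 4,000 px; longer skeletons use the two-sweep
  farthest-point heuristic, which is exact on trees (worm skeletons are
  paths).  Both routes are checked against brute-force all-pairs search
  in tests.
* **Area**: foreground count × pixel area.
* **Volume**: Σ over foreground pixels of pixel area × local channel
  height, a piecewise-constant lookup over the geometry layers by axial
  position.  "Height of each pixel" is read as the channel height at
  that position (the worm fills the channel vertically where trapped);
  the alternative reading — local worm thickness estimated from width —
  would systematically differ for thin worms in tall layers.

## Autofluorescence

Maximum-intensity projection over z; the threshold is the 95th percentile
(linear interpolation between order statistics) of the pooled in-mask
pixel intensities of the solvent-control (DMSO) worms of the same run;
per worm, the mean of in-mask pixels **strictly above** the threshold is
normalized per unit body length and per unit body area.  An integrated
(sum) variant is available behind a switch since "average
autofluorescence value per unit body length" is ambiguous between
mean/length and sum/length; the mean reading is the default.

## Dose–response statistics

Per-worm values are filtered by Tukey fences (quartiles by linear
interpolation, k = 1.5) on body length and autofluorescence jointly — a
worm outside either fence is removed everywhere.  Well summaries report
mean, SD (ddof = 1), SEM and CV = σ/µ; the control CV is the CV of
control-well means across replicates.

The 4-parameter variable-slope Hill model

    Y = Bottom + (Top − Bottom) / (1 + (X / EC50)^h)

is fitted by least squares (trust-region reflective, log-EC50
parameterization, slope sign chosen from the data trend); control doses
enter at `min_positive_dose / 100` so they anchor the zero-dose
asymptote on the log axis.  EC10 follows the "ECanything" transform
`ECf = (f/(100−f))^(1/|h|) · EC50` with f = 10, valid on the appropriate
branch for rising and falling curves.  The 95% CI profiles log EC10
against the F(1, n−p) sum-of-squares threshold (EC50 reparameterized
through EC10 and the slope), with a parametric bootstrap alternative; a
zero-residual fit degenerates to a point interval.

Two constraint modes exist: `"body"` fixes Bottom = 0 and `"af"`/`"free"`
leaves all four parameters free.  The report layer defaults **all**
endpoints to the free fit: body size saturates near the L4 size at high
dose, not at zero, and pinning Bottom = 0 on such data drives the fitted
slope toward 0 and the EC10 transform toward degenerate values (verified
numerically).  The Bottom = 0 mode remains available for responses that
genuinely vanish.

LOAEL: Shapiro–Wilk normality per group is reported (it does not switch
the test); Welch's heteroscedastic ANOVA (weights nᵢ/sᵢ², Satterthwaite
denominator df — equal to the squared Welch t for two groups) across all
groups; Dunnett's T3 comparisons of each dose against control (Welch t
with Satterthwaite df, studentized-maximum-modulus family adjustment —
analytic independence form by default, with a seeded Monte-Carlo variant
that preserves the shared-control correlation).  The LOAEL is the
smallest dose with adjusted p < 0.05; family-wise null calibration is
verified at ≈ 4–5% over 300 null simulations.

## Synthetic data: what it emulates and what it does not

No public image data exists for these devices, so the generator defines
the study conditions: sinuous worm bodies (centerlines integrated from
smooth random heading functions, so arc length equals the requested
length exactly; sine-tapered width profiles; capsule rasterization),
full/partial/empty occupancy at 81/14/5, dose-dependent body length
`Normal(µ(dose), cv·µ(dose))` with µ a Hill curve from 1,100 µm
(control D1 adults) to 650 µm (arrested young L4) with EC50 1.5 µM and
slope 2.5, biological CV 4% (the assay's observed control variability is
4–8%), channel walls and a fiduciary cross, defocus as Gaussian blur with
σ ∝ |z − z_focus| (the simplest model under which Laplacian focus
selection is correct), additive Gaussian noise, sub-worm-size debris
specks, and punctate gut-granule fluorescence confined to the medial 60%
of the centerline and inner 50% of the width whose intensity rises along
a second Hill curve (baseline 1.0 → 2.5 at saturation, EC50 2.5 µM).
Area and volume scale allometrically (width ∝ length), so they decline
more steeply with dose than length — matching the assay's observation
that area/volume are the more sensitive endpoints.

Not emulated: physical point-spread functions and shot noise, eggs and
embryos, worm motion beyond immobilization, optical vignetting, and real
annotation disagreement.  Passing tests therefore establish that the
pipeline is *self-consistent and correctly implemented* — that the
network can learn these images, that measured endpoints track the
generating parameters, that the statistics are calibrated — not that the
trained weights transfer to real micrographs.

## Problem sizes used by the test suite and acceptance script

Chosen for single-CPU runs: network experiments use 128×16 px channel
crops at 8 µm/px (2-level encoder, 32-dim tokens), 8-channel training
corpora, 400 overfit epochs and 80 fine-tuning epochs; the EC10 study
uses 200 simulations of the 12-dose × 5-replicate design at 5% noise;
null calibration uses 300 simulated experiments; device-scale generation
is exercised at the 288×32 px tiny preset (full 960-channel layout).
Full-resolution defaults remain available through configuration.

## Known limitations

* CPU-scale training only; no GPU path, no mixed precision, no windowed
  attention for the 7,584-token full-resolution grid.
* Geometry presets are placeholders pending device calibration.
* The two-sweep skeleton diameter is heuristic on skeletons with cycles
  longer than 4,000 px (not reachable for single worms in channels).
* Dunnett T3's analytic adjustment ignores the shared-control
  correlation (slightly conservative); the Monte-Carlo variant models it.
* The fluorescence model places granules independently; real gut
  granules cluster, so per-worm AF variance is optimistic.
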