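# wormseg

Segmentation, morphometry and dose–response statistics for *C. elegans*
immobilized in parallel microfluidic channels.

High-content developmental-toxicity (DevTox) assays image ~1,000 worms per
device run: 24 wells × 40 tapering trapping channels, each channel a
5,056-px-tall brightfield z-stack plus a fluorescence stack.  Turning those
images into toxicology endpoints needs four things done well: finding the
worm in every channel, deciding whether the channel holds a full worm at
all, measuring the body (length, area, volume, gut autofluorescence), and
fitting the dose–response.  `wormseg` implements that chain end to end for
toxicologists and imaging scientists running channel-device worm assays —
with a fully synthetic, seeded data generator so every stage is testable
without proprietary microscope data.

## The model and statistics at the core

**Segmentation network.** A 2.5D U-Net: the 2N+1 z-slices around the best
focal plane (Laplacian-energy selection) enter as input channels of a
ResNet-style convolutional encoder; at the bottleneck the feature grid is
flattened into tokens `X_e = Flatten(F_enc(X)) ∈ R^{(H/s)(W/s) × c}`
(s = 2^layers, c = 256), given learnable positional encodings, and
processed by a small pre-norm vision transformer — long-range attention
along a worm that spans thousands of pixels.  Two heads: a decoder with
skip connections produces a per-pixel soft segmentation over
{background, worm}; a pooled-attention classifier (one learnable seed
vector cross-attending over all tokens) labels the channel full / partial /
empty.  Training: AdamW (lr 2·10⁻⁴, weight decay 10⁻²), cosine annealing
with warm restarts (W₀ = 10, F = 2; restarts at epochs 0, 10, 30, 70,
150, …), segmentation loss only on full-worm samples.  Few-shot transfer
to a shifted worm population mixes n new samples 1:1 with original-domain
samples under a one-cycle schedule.  The network runs on a small numpy
autograd engine included in the package (`wormseg.nn`) — no GPU framework
required.

**Morphometry.** Threshold 0.50 → largest connected component → body
length as the longest geodesic path through the skeleton graph, area as
pixel count × pixel area, volume as Σ pixel area × local channel height
(piecewise-constant layer lookup referenced to the device's fiduciary
mark).

**Dose–response.** Tukey-fence outlier removal (1.5·IQR), well summaries
(µ, σ, SEM, CV = σ/µ), 4-parameter variable-slope Hill fits

    Y = Bottom + (Top − Bottom) / (1 + (X/EC50)^h),
    EC10 = (10/90)^(1/|h|) · EC50

with profile-likelihood 95% CIs, and LOAEL via Welch's ANOVA with
Dunnett-T3 comparisons against the solvent control (smallest dose with
adjusted p < 0.05).

## Worked example

Simulate a small device, train briefly, and run inference and statistics
(the `--preset tiny` scene is a 288×32 px channel geometry that keeps every
relation of the full 5,056×353 px device):

```bash
wormseg simulate --out run/data --seed 1 --wells 4 --preset tiny
wormseg train    --data run/data --out run/model.npz --epochs 120 --batch-size 8
wormseg infer    --data run/data --model run/model.npz --out run/pheno.csv \
                 --geometry 4L --min-area-px 300
wormseg fluor    --data run/data --phenotypes run/pheno.csv --out run/af.csv
wormseg stats    --phenotypes run/pheno.csv --fluor run/af.csv --out run/stats.json
```

`pheno.csv` holds one row per channel (`worm_id, predicted_class,
length_um, area_um2, volume_um3, qc_flags, ...`); `stats.json` holds well
summaries, EC10 fits, LOAELs and control CVs.  The same pipeline through
the Python API, on a dose–response population drawn from the generator's
study conditions (12 methylmercury doses 0.5–9.0 µM + DMSO control, 5
replicates):

```python
import numpy as np
from wormseg.synthetic_data import DosePlan, simulate_dose_response
from wormseg.cli import dose_response_report

plan = DosePlan()           # Hill: 1100 um (control) -> 650 um, EC50 1.5 uM
df = simulate_dose_response(plan, np.random.default_rng(1),
                            n_replicates=5, n_worms_per_well=20)
df["predicted_class"] = "full"
report = dose_response_report(df, seed=1)
print(report["ec10"]["length_um"]["ec10"])   # 0.625
print(report["ec10"]["volume_um3"]["ec10"])  # 0.552
print(report["loael"]["length_um"]["loael_um"])  # 0.891
print(report["control_cv"]["length_um"])     # 0.0556
```

The printed numbers are one seeded run: the fitted EC10 for body length
(0.625 µM) sits within sampling error of the generating curve's analytic
EC10 (0.623 µM); volume — which scales as ~L³ — shows toxicity at a lower
concentration than length (0.55 µM), the expected sensitivity ordering of
the endpoints; the LOAEL lands at the second tested dose (0.89 µM), where
the mean-length decline first clears the well-to-well biological
variability (control-well CV 5.6%).

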