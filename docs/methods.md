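# Methods

`mrsisr` builds synthetic brain metabolite maps from tissue anatomy, trains
an attention-based convolutional network to upscale them four-fold
(32×32 → 128×128), and quantifies the gain over classical interpolation.
This note documents the models, the defaults and the reasoning behind the
open design choices.

## Why synthetic maps

High-resolution MRSI metabolite maps are essentially unobtainable in the
clinic: acquisitions at 128×128 are prohibitively slow, so 32×32 grids are
the norm. Supervised super-resolution therefore has no real paired training
data. The workaround is to *synthesize* high-resolution maps from anatomy:
tissue compartments (GM, WM, CSF) have distinct, literature-established
metabolite concentrations, and glioma lesions have distinct concentrations
and diagnostic ratio ranges. Given a tissue segmentation, a plausible
metabolite map is a concentration-weighted sum of compartment occupancies.

## Phantom anatomies

The phantom generator replaces real tumor-imaging anatomies (which would
require external data and a segmentation tool) with a seeded ellipsoidal
head model per subject:

- an elliptical brain outline with per-subject axes, a cortical GM band, a
  central WM region, ventricular and peripheral-rim CSF;
- soft partial-volume occupancies obtained by Gaussian-smoothing the
  one-hot compartment masks with σ = 0.7 px. Smoothing one-hot planes
  conserves their sum, so gm + wm + csf ≤ 1 holds exactly. The sub-voxel σ
  emulates the ≈1-voxel transition width of partial-volume estimates from
  automated tissue segmentation; a `binarized()` accessor gives hard labels;
- a contiguous tumor blob: thresholded smoothed noise around a random
  center, reduced to the connected component containing the center, with a
  disk fallback so the lesion is never empty. Each subject carries a grade
  label (LGG or HGG) assigned at generation time;
- a FLAIR-like slice: tissue-weighted intensities (GM 0.75, WM 0.50,
  CSF 0.12) under a smooth multiplicative bias field and mild noise, with
  tumor pixels set hyperintense (≈1.05) so tumor-containing slices satisfy
  the selection rule below;
- smooth through-plane variation: slice geometry shrinks away from the
  stack center, mimicking movement through the head.

Slice selection keeps slices whose mean FLAIR intensity over tumor pixels
strictly exceeds the whole-slice mean, ordered by index and capped at 10 —
the rule used to pick 5–10 tumor-bearing axial slices per subject.

What the phantom does *not* model: 3-D anatomical realism, registration,
skull-stripping, acquisition artifacts, field inhomogeneity, or spectral
effects (lineshapes, baselines). Passing tests on phantom data therefore
demonstrate the pipeline's correctness and the advantage of learned
upscaling on piecewise-smooth compartmental images with sharp boundaries —
not clinical performance.

## Concentration table and map synthesis

The table holds, per metabolite (tCr, tCho, NAA) and compartment (GM, WM,
Tumor), a literature range in mM with its point estimate — the range
midpoint, e.g. GM tCr 6.4–9.7 → 8.05 — and, for the ratios tCho/NAA and
tCho/tCr, tumor ranges plus nontumor GM/WM rows. CSF is fixed at zero
concentration. Two details matter:

- **Grade thresholding.** Tumor ratio ranges are split at their average:
  LGG lesions draw from the lower sub-range, HGG from the upper
  (tCho/NAA splits at 2.35, tCho/tCr at 1.75). Deterministic mode uses the
  sub-range midpoint; sampled mode draws uniformly within it, once per
  subject and map type (the lesion carries the concentration, not the
  slice).
- **Nontumor ratio estimates are used as printed** (GM/WM tCho/NAA 0.20 /
  0.22; tCho/tCr 0.80 / 0.50), although not all are range midpoints; the
  printed values are treated as authoritative.

A high-resolution map is `C_GM·gm + C_WM·wm + 0·csf`, with the tumor value
*replacing* the tissue contribution inside the mask. A strictly additive
form would double-count tissue under the lesion; replacement matches the
idea of regionally distinct concentrations. An `tumor_additive` flag
restores the additive form for fidelity experiments.

Maps are normalized to [0, 1] by their maximum (an all-zero map is left
unchanged). Low-resolution counterparts are 4×4 block averages — chosen
because coarse MRSI voxels integrate signal over their volume — which makes
nearest-neighbor upscaling the exact inverse on block-constant images and
conserves the global mean exactly. With the default 220 mm field of view,
voxels are 1.719 mm (128 grid) and 6.875 mm (32 grid) on edge at 10 mm
slice thickness.

Each training example pairs the normalized HR map (target) with a
2-channel LR input: the block-averaged map plus the block-averaged,
min-max-normalized FLAIR slice. FLAIR conditioning enters at LR because
the network input grid is 32×32.

## Network

Input 2×32×32 → output 1×128×128. A 3×3 convolution lifts the input to
`base_channels` (default 48); the body stacks `n_pairs` (default 8)
HFAB→GDFN pairs; two long skip connections re-inject the shallow features
at the body midpoint and the body end; a sub-pixel head (two stages of
3×3 conv ×4 channels + 2× pixel shuffle with ReLU, then a 3×3 conv to one
channel) reconstructs the HR map. The output passes through a sigmoid —
the codomain of normalized maps — so the large, exactly-zero background
saturates cleanly; a linear head with clipping to [0, 1] at evaluation is
available by configuration, but in desk-scale experiments it leaves
low-amplitude background ripple that the structural-similarity metric
punishes severely while barely moving the MSE, and its training is
markedly more seed-sensitive. Output clipping to [0, 1] at evaluation is
kept for both heads (a no-op under the sigmoid).

- **HFAB** (high-frequency attention block): a residual block whose
  attention branch — BatchNorm → 3×3 conv halving channels → ERB → 3×3
  conv restoring channels → BatchNorm → sigmoid — yields a per-position
  gate in [0, 1]; output = x·gate + x. BatchNorm in the branch gives the
  gate global statistics at inference for free.
- **ERB** (enhanced residual block): 1×1 expansion (×2), 3×3 convolution
  with ReLU, 1×1 contraction, residual add.
- **GDFN** (gated feed-forward block): two parallel 1×1 (×2) + 3×3
  depthwise branches; the GELU of one gates the other by element-wise
  product before a 1×1 projection back and a residual add.

"Eight HFAB pairs" is read as eight (HFAB→GDFN) pairs; `n_pairs` is
configurable so the sixteen-single-block reading can be tested. Channel
widths, skip endpoints and the upsampler are not pinned down by the
architecture description; the defaults here were chosen so the model lands
on the ~650 k trainable-parameter budget (48 channels → 648,769) and uses
the standard parameter-efficient sub-pixel upsampler for ×4.

Initialization is He throughout, with two conditioning measures: the final
convolution of each residual branch starts at 0.1× scale and the gate's
second BatchNorm starts with β = −2 (gates ≈ 0.12), keeping the deep
residual body near-identity at initialization — without this, activations
grow multiplicatively across pairs and float32 forward passes overflow.

### NumPy engine

The network and its training run on a small in-package engine
(`mrsisr.nn`): convolutions, depthwise convolutions, batch normalization
with running statistics, sigmoid/GELU/ReLU, pixel shuffle, and Adam, each
with hand-written backward passes verified against central finite
differences in the test suite. Arrays are stored channel-first (C, B, H, W)
so each 3×3 convolution becomes one well-shaped GEMM per kernel offset on
contiguous flat views (zero padding makes the flat-index row wrap-around
terms vanish); this keeps single-core training of the reduced model at
about 1 s per 12-example batch.

## Training

Log-cosh loss, mean over pixels: quadratic (≈ ½·residual²) for small
residuals, linear (≈ |r| − log 2) for large ones, computed stably as
|x| + log1p(exp(−2|x|)) − log 2; its gradient is tanh(residual)/N.
Adam optimizes it; the train/validation split is at the subject level
(30 % of subjects to validation) so no subject's slices leak across the
split; augmentation applies seeded 90°-multiple rotations and flips
identically to inputs and target (interpolation-free, hence value-exact);
the checkpoint kept is the best-validation one. The full-scale protocol
(batch 24, learning rate 1e−5, 100 epochs, augmentation on) is the
`TrainConfig` default.

## Baselines and metrics

Nearest-neighbor replication and spline interpolation (cubic by default,
order configurable), the latter with reflect boundaries and the half-pixel
block-center alignment convention (`grid_mode`), clipped to [0, 1] for
normalized inputs since cubic splines overshoot at edges. Both are
deterministic; factor 1 is the identity.

Per-map metrics: MSE, RMSE = √MSE, PSNR = 20·log10(MAX) − 10·log10(MSE)
with MAX fixed at 1.0 for normalized maps (zero MSE reports +∞), and SSIM
with an 11×11 Gaussian window (σ 1.5), k₁ = 0.01, k₂ = 0.03, unit dynamic
range — computed through scikit-image with exactly these settings and
cross-checked against a brute-force sliding-window implementation in the
tests. LPIPS needs pretrained perceptual weights, so it is a plug-in: a
registered backend receives 3-channel replicated inputs rescaled to
[−1, 1]; with no backend the metric is simply omitted from records.

Method comparison uses two-sided Mann–Whitney U tests per metric: exact
enumeration of the U distribution for tie-free samples of size ≤ 8, and
the normal approximation with tie and continuity corrections otherwise
(cross-checked against scipy); summaries report mean and sample (n−1)
standard deviation; significance threshold p < 0.05, no multiple-testing
correction.

## The desk-scale comparison experiment

`mrsisr.experiments.run_comparison` reproduces the study design at sizes a
single CPU handles in minutes: 60 phantom subjects (alternating LGG/HGG),
3 slices each, sampled concentrations; 42 subjects for train/validation
and 18 held out (630 and 270 map pairs); a reduced model (16 channels,
4 pairs, 48,001 parameters); 14 epochs at batch 8, learning rate 5e−3,
augmentation off. The reduced conditions were chosen for the compute
budget and for robustness across seeds: the smaller batch buys more
optimizer steps per epoch at a learning rate gentle enough to converge
reliably, and at a few hundred training steps augmentation costs more
convergence than the generalization it buys (the full-scale defaults keep
it on). Evaluation compares model, nearest and spline per held-out map
and tests all pairs. With these defaults the learned model clearly
outperforms both interpolators on every metric and seed tried (seed 1:
MSE 0.0005 vs spline 0.0024 vs nearest 0.0053; SSIM 0.97 vs 0.88 vs 0.83;
PSNR 32.9 vs 26.7 vs 23.6 dB; model-vs-nearest MSE p ≪ 0.001; seeds 2
and 3 within a few percent of these) — the same ordering as the
full-scale study conditions this emulates.

### Capacity sanity check

`mrsisr.experiments.overfit_single_batch` memorizes one batch of eight
paired examples (two phantom subjects) with a shallow reduced model
(16 channels, one block pair) under Adam with β = (0.85, 0.98) and a fixed
step-decay ladder from 1e−2 down to 3e−4, stopping once the training loss
falls below 1e−4 (around step 350 with the sigmoid head, about a minute of
optimization on one CPU). The shallow variant is used deliberately: the
deeper reduced model reaches the same loss but needs several times more
steps — an optimization-conditioning effect of the near-identity-
initialized residual stack, not a capacity limit.

## Numerical notes and limitations

- All randomness flows through seeded NumPy generators; phantom
  generation, dataset builds, initialization, batching and augmentation
  are bit-reproducible for a given seed on one platform.
- Normalization divides by the map maximum; an all-zero map stays zero and
  is flagged normalized. PSNR of identical maps is reported as +∞ rather
  than an error.
- SSIM window parameters follow the Wang et al. convention; with a
  weighted window the covariance normalization is 1 (no n−1 factor).
- The spline baseline's variant and alignment are pinned (cubic,
  reflect, half-pixel centers) so metric values reproduce bit-for-bit.
- Training on a single CPU constrains the experiment sizes above; the
  architecture and protocol scale unchanged to the full study sizes given
  more compute.
- Phantom-trained models are not expected to transfer to clinical MRSI;
  the package's claims are about the pipeline and the relative ordering of
  upscalers under its stated generative model.
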