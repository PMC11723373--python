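# Methods

## Overview

`eegnet` implements an EEG seizure prediction/detection pipeline built
around a *contractive spike-and-slab convolutional deep belief network*
(CssCDBN) with a self-attention head, trained under a dual-task
(classification + Siamese verification) objective. The pipeline stages are

1. **Spectral preprocessing** — multichannel scalp EEG → 3×64×64 band-power
   images (theta/alpha/beta),
2. **Generative pretraining** — greedy layer-wise contrastive-divergence
   training of spike-and-slab convolutional RBMs,
3. **Discriminative fine-tuning** — the pretrained stack is treated as a
   feed-forward network with an attention-based classifier and trained
   end to end on the combined classification/verification loss,
4. **Evaluation** — sensitivity, false-positive rates (per sample and per
   monitored hour), accuracy, per-event prediction times, stratified
   k-fold cross-validation.

## Spectral preprocessing

Recordings follow scalp-EEG conventions: 23 bipolar derivations sampled at
256 Hz, annotated with interictal / preictal / ictal intervals. Each
interval is cut into non-overlapping 2-second windows (trailing remainders
discarded); each window is detrended per channel (mean removal, so DC does
not leak into theta), Fourier transformed, and summarised by the summed
squared DFT magnitudes inside theta (4–7 Hz), alpha (8–13 Hz) and beta
(13–30 Hz).

The 23 per-band channel powers are placed on a 5×5 scalp grid that follows
the double-banana bipolar montage (frontal row at the top, left hemisphere
on the left; the two cells with no derivation take their nearest assigned
neighbour's value). The grid is resampled to 64×64 by bicubic spline
interpolation whose knots sit on output pixels {0, 16, 31, 47, 63}, so the
resampling is an exact interpolant (knot pixels reproduce the inputs;
constants and polynomial ramps up to degree 3 are reproduced exactly).
Because spline interpolation is linear in the data, the grid→image map is
precomputed once as a 4096×25 operator and imaging an entire recording
reduces to one matrix product.

Two labelled datasets mirror the study conditions: the binary *prediction*
set (per patient, 180 min preictal + 180 min interictal → 10,800 images
per patient) and the four-class *detection* set (per patient, 30 min each
of interictal / PreI / PreII / ictal, where PreI and PreII are the earlier
and later halves of the 60-min preictal window → 900 images per class per
patient). Builders either return the images in memory, stream them to
HDF5, or — for full-scale count verification — compute every image and
retain only labels and counts.

ZCA whitening is provided as its own transform (`fit_zca` /
`ZCAWhitening`): eigendecomposition-based, `W = U diag((e+ε)^-1/2) Uᵀ`
with ε (default 1e-5) added to the eigenvalues; it is the whitening
closest to the identity and is exactly invertible for ε > 0. Whitening is
fit on the training split only. The classifier's default preprocessing is
per-pixel standardisation of log band power (`log1p`, applied when inputs
are nonnegative); band power is heavy-tailed over several decades and
training directly on raw power is numerically hostile. Full ZCA over the
12,288-dimensional flattened pixel space is supported but not part of the
default classifier path: its eigendecomposition cost is cubic in the pixel
dimension, so it is practical for cropped or downsampled images rather
than full 3×64×64 sets.

## The spike-and-slab convolutional RBM

One layer couples an L-channel real visible field `v` to K feature maps of
binary *spike* units `h` (feature present?) and real-valued *slab* units
`s` (feature magnitude) through shared convolution kernels `w`:

    E(v, s, h) = − Σ_{l,k,ij} (v^l ∗ w^{l,k})_ij h^k_ij s^k_ij
                 − Σ_k b^k Σ_ij h^k_ij
                 + Σ_{l,mn} (v^l_mn − c^l)² / (2σ²)
                 + ½ Σ_{k,ij} a^k (s^k_ij)²,

with `∗` valid-mode cross-correlation, spike biases `b`, visible biases
`c`, visible noise scale σ and slab precision penalties `a > 0`. All
conditionals are exact and closed-form:

* spikes: `p(h = 1 | v) = σ_logistic(z²/(2a) + b)` with `z` the
  channel-summed filter response — the slab integrates out analytically,
  producing the squared-response activation (the square applies to the
  channel-summed response, which is the form consistent with the energy;
  the enumeration oracle in the tests pins this),
* slabs: `s | v, h ~ N(z h / a, 1/a)`,
* visibles: `v | s, h ~ N(σ² · conv_T(h⊙s) + c, σ²)` where `conv_T` is
  the adjoint (flipped-kernel full) convolution.

**Dual-variable probabilistic max-pooling.** Hidden units are partitioned
into pool×pool blocks with the constraint that at most one spike per block
is active; the block-level spike posterior is a categorical over block
positions plus an "off" state (softmax of the activation arguments with an
implicit zero logit). The pooled slab is Gaussian with the block *maximum*
of the unit means. The pooled layer output is the elementwise product of
the sampled pooled spike and pooled slab. Every hidden unit belongs to the
block `(⌊i/pool⌋, ⌊j/pool⌋)`, so trailing rows/columns form smaller blocks
and the constraint covers the whole grid; the pooled *map* keeps only the
`⌊H/pool⌋` full blocks, which is what reproduces the default shape chain
64 → 31 → 15 → 7 → 3.

**Training** is CD-k (default k = 5, learning rate 0.01, batch 20): k
alternating Gibbs sweeps from the data batch; the positive phase uses
expected sufficient statistics given the data (`E[h]`, `E[hs] = q z / a`,
`E[s²] = 1/a + q z²/a²` under the pooled posterior), the negative phase
the same expectations at the chain-end visible sample (Rao-Blackwellised —
lower variance than raw sampled statistics, while still anchored to the
sampled chain end). Verified property: the CD gradient estimate
sign-agrees with the exact enumerated log-likelihood gradient on ≈97% of
parameters across 20 tiny seeded instances.

**Contractive penalty.** The regulariser is the squared Frobenius norm of
the Jacobian of the (unpooled) spike probabilities with respect to the
visible input. For this model it has the closed form
`Σ_k ‖w^k‖²_F Σ_ij [q(1−q) z/a]²_ij`, and its gradient (with respect to
`w` only; biases are not regularised) is produced by the package's
gradient engine and finite-difference checked. Layer coefficients default
to 0.1, 0.1, 0.2, 0.2 for the 4-layer stack.

**Numerical choices.** σ is fixed at 1 (inputs are standardised); `a` is
learned in log space to stay positive, one value per feature map
(broadcast over positions — the weight-sharing logic of convolution);
kernels start `N(0, 0.01²)`, spike biases at −1 (sparse start), `c = 0`,
`a = 1`. The squared-response energy can produce a positive feedback loop
(larger kernels → larger responses → larger sampled slabs), so updates are
clipped to a global gradient norm of 5 by default; training was stable at
learning rate 0.01 in all experiments with clipping on.

## Stacking and deterministic fine-tuning

Layers are pretrained bottom-up; each layer's training input is the pooled
hybrid (spike ⊙ slab) map of the layer below, computed by the
deterministic mean-field forward. The default configuration is 36/64/128/
128 kernels of size 3 (padding 1 above the first layer) with 2×2 pooling,
ending in a 128×3×3 hybrid map.

After pretraining, the stack runs as a feed-forward network: spikes become
`h = relu(z²/(2a) + b)`, slabs `s = z h / a` plus, in training mode only,
a seeded noise term (scale `1/a` as printed in the reference formulation;
a flag switches to the conditional's standard deviation `1/√a` — the two
differ whenever a ≠ 1, an inconsistency in the source formulation that the
package exposes rather than hides). Hybrid maps are `h ⊙ s` (continuous —
no binarisation, preserving gradients) and pooling is the deterministic
block max of the hybrid map. Fine-tuning trains `w`, `b` and `log a` of
every layer; `c` and σ are frozen.

**Activation calibration.** The relu of the squared-response argument is
dead wherever `z²/(2a) + b < 0`; after short generative pretraining with a
sparse bias start this can silence entire feature maps, and unlike the
logistic the relu passes no gradient to revive them. At the pretrain →
fine-tune hand-off the package therefore raises each feature map's bias by
the smallest amount that brings the 90th percentile of its activation
argument (over a calibration batch) up to 0.05. Biases are only ever
raised, only as far as needed, and the step can be disabled
(`calibrate=False`).

## Attention head and classifier

The final hybrid maps are flattened row-major into tokens (9 tokens of
width 128 for the default stack) with learned positional embeddings, then
passed through one Transformer encoder block: single-head scaled
dot-product self-attention and a two-layer perceptron (hidden width 2d),
each residual with pre-norm layer normalisation. Attention weights are
softmax-normalised by default — the only fully specified, numerically
stable choice; `attention_norm="none"` keeps raw scaled dot products for
ablation. A final layer normalisation precedes mean-pooling of the
tokens; this bounds the pooled representation (and hence the logits)
regardless of the activation scale coming out of the stack. The pooled
vector feeds a linear softmax classifier and, L2-normalised, serves as the
verification feature.

With all transform weights zero the encoder block is the identity on
tokens and the classifier outputs the uniform distribution; attention rows
always sum to one.

## Dual-task fine-tuning

Each even batch (default 20) is split into two halves and paired at
random; a pair's verification label is 1 iff the class labels agree. With
features `f1, f2` and `D = ‖f1 − f2‖`:

* same class: `½ D²`,
* different class: `½ max(0, δ − D)²` (margin δ = 1 on the L2-normalised
  features, making the margin scale-free).

The per-pair objective is `CE(a) + CE(b) + c_ver · loss_ver` with
`c_ver = 0.11`, averaged over pairs (the averaging convention only
rescales the learning rate) and minimised with Adam (lr 0.01, β = 0.9/
0.999, ε = 1e-8). The main loss is categorical cross-entropy, which
reduces exactly to the binary form at two classes (needed because the
detection task has four classes). Both Siamese branches share parameters
by construction — they run through the same tensor objects. Non-finite
losses abort training and restore the last epoch's parameters. A printed
auxiliary coefficient `c_ide = 0.07` belongs to an identification task not
defined in this framework and is recorded here as inert.

Gradients come from a small reverse-mode engine written for this package
(`eegnet._autodiff`): a tape of numpy primitives (convolution, pooling,
matmul, softmax, layer norm, elementwise ops) each finite-difference
checked in the test suite. No external autodiff framework is required.

## Evaluation

Binary metrics: sensitivity TP/(TP+FN), per-sample FPR FP/(TN+FP),
accuracy (trace/total in the multiclass case). Because a per-sample ratio
cannot express alarms per hour, the per-hour FPR counts *alarm events* —
positive interictal samples closer than a 2-min refractory window merge
into one alarm — divided by monitored interictal hours. A seizure counts
as predicted when at least one preictal sample is classified positive; its
prediction time is the interval from the first positive sample to the
annotated onset (missed events are flagged and excluded from the mean).
Cross-validation is stratified k-fold (default 10), seeded; an optional
`groups` argument keeps all samples of one seizure event in a single fold,
guarding against leakage of a seizure's preictal window across train and
test.

## Synthetic data

The generator emulates the *structure* of the clinical recordings, not
their physiology: 23 channels at 256 Hz, spectrally shaped Gaussian noise
with a 1/f background (exponent 1.0) and in-band power boosts per class
(band-limited noise rather than pure tones, so spectra are not
degenerate). Class gains multiply in-band *power*; at gain 1 the in-band
oscillation power is 8× the local background, so a 3× theta gain yields a
measured theta-power ratio of ≈ (1+24)/(1+8) ≈ 2.8 between classes.
Records are scaled by the gain-free baseline RMS (≈10 µV), so class gains
survive in absolute power. The ictal class adds high-amplitude 3–5 Hz
rhythmic bursts with a 50% duty cycle. Cohorts draw per-patient sub-seeds
from a seed tree, and everything is byte-reproducible given the seed.

Defaults follow the study conditions: 10 patients; per patient three
60-min preictal records plus 180 min interictal (prediction set) and
60 min preictal + 30 min ictal + 30 min interictal (detection set).

What passing tests on this data do and do not show: classes differ by
stationary band-power signatures, so separability is essentially linear
once band power is measured — synthetic results demonstrate that the
pipeline is wired correctly end to end (counts, shapes, training dynamics,
metric computation), not that the model attains clinical-grade
discrimination on real EEG, where class differences are subtler and
non-stationary.

The same module provides tiny RBM instances (1 visible channel, 3×3
field, 2×2 kernels) with brute-force oracles: all spike configurations are
enumerated, slabs integrate out analytically per unit, and for the exact
likelihood the joint (v, s) Gaussian integral is evaluated per
configuration, giving exact posteriors and exact likelihood gradients to
test against.

## Problem sizes used in the shipped checks

Full-duration dataset construction runs all 10 synthetic patients at the
stated durations (counts only retained). The end-to-end classification
check uses a deliberately reduced model — one CssCRBM layer of eight 3×3
kernels with 4×4 pooling, ~200 training images from a 2-patient cohort at
4 min per class, 3 pretraining epochs and 10 fine-tuning epochs — chosen
so the whole pipeline exercises every stage at desk scale; with the
default well-separated class gains it reaches held-out sensitivity ≥ 0.9.
The 4×4 pooling keeps the token count seen by the attention head near its
design regime (the default 4-layer stack ends at 3×3 = 9 tokens; a
single-layer stack with 2×2 pooling would emit 961 tokens and a
[batch × 961 × 961] attention graph).

## Known limitations

* The fine-tuned forward is a mean-field surrogate, not exact inference in
  the generative model; the hybrid map uses continuous relu values.
* The per-hour false-alarm rate depends on the refractory merge window
  (2 min default); the sample-to-event rule is a package choice.
* Full-pixel ZCA is cubic in the flattened dimension and intended for
  reduced image sizes.
* CD training of the squared-response energy is stable only with gradient
  clipping or small learning rates; persistent CD and partition-function
  estimation are out of scope.
* The synthetic generator makes no claim of physiological realism; see
  above for what synthetic passes imply.
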