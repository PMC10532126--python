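# Methods

## Problem and model

The quantity of interest is the respiratory rate (RR, breaths per minute)
of a seated subject filmed by a low-resolution long-wave-infrared camera
(nominally 80 × 60 px at 8.7 Hz, 14-bit intensity counts). Exhaled air is
warmer than inhaled air, so the nostril region's intensity oscillates at
the breathing frequency; one breathing episode is one full
inhalation–exhalation cycle.

Two estimators are implemented.

**Classical spectral baseline.** Per frame, the nostril-region pixels are
aggregated to one value (arithmetic mean, or sample skewness for a
shape-sensitive variant); the resulting series is mean-subtracted and
band-pass filtered (zero-phase Butterworth, order 3, default pass band
0.1–0.85 Hz = 6–51 bpm, covering adult resting rates); the rate is
60 × the frequency of the dominant magnitude-spectrum peak, refined by
4× zero-padding and parabolic interpolation of log-magnitudes. On clean
periodic input its error is bounded by the spectral resolution `fps/T` Hz
(`60·fps/T` bpm), and the interpolation typically does much better.

**Two-pathway convolutional regressor.** The same window of frames is read
at two temporal strides: a *dense* view (every `alpha`-th frame; 32 frames
for a 128-frame window at `alpha=4`) and a *sparse* view (every `beta`-th
frame; 8 frames at `beta=16`). Each view feeds a 3-D ResNet-style branch
of bottleneck blocks (counts 3+4+6+3 for the ResNet50 backbone, 3+4+23+3
for ResNet101). The dense branch is narrow (its channel widths are
`channel_ratio` = 1/8 of the sparse branch's, mirroring the 8-vs-64 stem
filter plan) and carries a temporal kernel of 5 in its stem and 3 in its
residual stages; the sparse branch is wide, with a temporal-1 stem and
temporal kernels 1/1/3/3 across stages. After the stem and after every
residual stage, a lateral fusion convolution (temporal extent
`fusion_kernel_t`, temporal stride `beta/alpha`, output 2× its input
channels) carries dense-branch features across and is concatenated onto
the sparse branch. Both branches are globally average-pooled over space
and time, concatenated, passed through dropout and a single linear unit —
an unbounded scalar in bpm, trained as a regression (no softmax).

Two knobs specific to thermal data are exposed. Heat diffusion blurs
thermal images, so informative spatial structure is spread wider than in
visible light; the stem/residual spatial kernels are therefore enlargeable,
with canonical pairs (5,3), (7,5), (9,7). Their one-dimensional analytic
effective receptive fields, computed over the spatial stack (1 stem + 16
residual spatial convolutions) at unit strides, are 37, 71 and 105 pixels;
the layer-count approximation for a residual net is `L = (D − d)·q`. The
unit-stride convention makes the ERF a pure function of the kernel plan —
an analysis artifact for comparing configurations; the network itself
downsamples spatially (stride 2 at the stem and at stages 2–4). The second
knob is the fusion kernel's temporal depth (5–15): how much breathing-cycle
context crosses between pathways per fusion point.

### Slow/Fast naming

In the two-stream action-recognition family the "Slow" branch is the
wide, temporally sparse one and "Fast" the thin, temporally dense one,
with fusion Fast→Slow. For breathing data the same geometry applies, but
sweep tables in the literature attach "slow" to the `alpha` (dense)
stride, so the labels are ambiguous. This package avoids them: views and
branches are named *dense* (stride `alpha`, thin) and *sparse* (stride
`beta`, wide), and fusion runs dense→sparse. `channel_ratio` is the
dense/sparse width ratio (default 1/8).

## Losses and evaluation

Training losses: MSE, MAE, RMSE and weighted MSE
`WMSE = reduce_i w·(Y_i − Ŷ_i)²` with scalar weight `w` (per-sample weight
vectors are supported as a hook; `w=1` reduces WMSE to MSE). `reduction`
is the batch mean or the batch maximum of per-sample terms, applied per
batch; for RMSE the root follows the reduction, so max-reduced RMSE is the
largest absolute residual. Evaluation uses
`RMSE = sqrt(Σ(RR_est − RR_gt)²/N)`, reported with the standard deviation
of per-sample absolute errors as its spread figure.

Cross-validation is subject-grouped: subjects are shuffled under a seed
and dealt round-robin into k folds, so all recordings of one volunteer
share a fold and fold sizes differ by at most one subject. Any
train/validation pair with a common subject id raises an error. The
aggregate RMSE is the mean of per-fold RMSEs.

## Synthetic data

Real thermal face datasets of this kind are small and private, so the
package generates its own. A sequence is a static face template — a smooth
warm blob on a cooler background with subject-specific geometry and
baseline, not rendered anatomy — plus a breathing modulation confined to a
fixed lower-central "nostril" rectangle recorded in the metadata. The
modulation is `amplitude · waveform(2π·(rr/60)·t + phase)` where the
waveform is a cosine (or a skewed cosine with a faster exhale edge,
because real nostril traces have asymmetric peaks). Its spatial profile
inside the ROI is mean-one but non-uniform (an off-centre bump), so the
ROI mean carries exactly the nominal amplitude while shape-sensitive
aggregators such as skewness also see the oscillation. Per-pixel Gaussian
noise and a linear baseline drift are added, then frames are quantised
(round-half-even) and clipped to the 14-bit range. Fixed seeds give
bit-identical output.

Cohort defaults mirror a small LWIR study population: 15-second recordings
at 8.7 Hz and 80 × 60 px, rates drawn uniformly from 6–30 bpm, phase
uniform, modulation amplitude 600 counts and sensor noise 20 counts
(a strong but not noise-free signal; the classical pipeline's defaults
were chosen for this regime). `gt_breaths` is real-valued
(`rr·duration/60`); labels are expressed in bpm throughout, so windows of
different lengths stay comparable.

What the simulator does *not* emulate — head motion, nostril displacement,
radiometric calibration, flow physics of exhaled CO₂, facial expression —
bounds what passing tests show: they demonstrate that the estimators
recover periodic nostril-region intensity modulation under sensor noise
and drift, not robustness to motion or anatomy.

## Training recipe and desk-scale study

The learning-rate schedule is a constant warmup rate for `warmup_epochs`
(default 64 epochs at 5·10⁻⁵, the best swept values) followed by a
post-warmup rate (default 10× warmup) with cosine decay. Epoch count,
batch size and optimiser are not part of the swept vocabulary and are this
package's own defaults (100 epochs, batch 8, SGD momentum 0.9), all
config-exposed; the desk-scale experiments below use Adam, which converges
far more reliably at small width. One master seed fans out (via
`SeedSequence`) to simulator, fold shuffling, weight initialisation and
batch shuffling, so each stage can be replayed independently.

The full-scale network (224 × 224 × 3 inputs, width multiplier 1) is far
beyond a single-CPU numpy stack, so the package's experiments run a
width-reduced proxy: `width_multiplier = 1/16`, 32 × 32 single-channel
input, 64-frame windows at 8 fps with `alpha=2`, `beta=8`, kernel
configuration (5,3), fusion kernel 5. The learnability study trains on a
synthetic cohort of 9 subjects × 4 recordings (RR uniform on 6–30 bpm,
noiseless), about 220 training clips from 7 subjects with 2 subjects held
out. Multiple recordings per subject matter: with one recording per
subject the network can regress the label from the subject's static face
template alone and fails on held-out subjects; several rates per face
make the temporal signal the only label-predictive feature. The pass
criterion is held-out RMSE below 3 bpm and below the constant-mean
predictor's ≈ 24/√12 ≈ 6.93 bpm — a learnability surrogate, not a
reproduction of full-scale accuracy figures.

## Numerical choices and edge cases

* Frame counts use half-up rounding (`15 s × 8.7 Hz → 131 frames`);
  resampling picks nearest-frame indices, never interpolates.
* The sliding-window stride defaults to one second of frames (8 at the
  8 Hz target rate), i.e. adjacent windows share everything but one
  second — the reading of "1 s overlap" that yields many windows per
  short recording. `gt_breaths` stays real-valued; integer self-counted
  breath labels can be emulated by rounding it at ingestion.
* Clip normalisation divides counts by 2¹⁴ − 1; spatial resizing is
  bicubic; the single thermal channel is replicated when a multi-channel
  input is requested. Pathway views anchor at frame 0 (no temporal jitter).
* The convolution engine materialises no im2col buffer; each kernel tap is
  a strided slice contracted by matmul, with the exactly mirrored
  scatter-add backward pass. Batch norm is a single fused primitive;
  running statistics make inference deterministic and batch-independent.
* The final linear layer starts at zero weights with its bias set to the
  training-label mean, so early training predicts a sensible constant.
* Degenerate inputs fail loudly: non-positive durations/rates, ROIs
  outside frame bounds, pixels past the 14-bit maximum, pass bands beyond
  Nyquist, sub-2-pixel ROIs, subject leakage, non-divisor pathway strides,
  and numerically-constant spectra (no-peak) all raise typed errors.
* `kfold_split` ties are broken by sorted subject id before shuffling;
  grid-search ties are broken by smaller parameter count.

## Known limitations

The autodiff engine is single-threaded numpy: adequate for the desk-scale
proxy, two orders of magnitude from GPU training; the full 224 × 224
configuration is constructible and runs forward passes, but training it is
impractical here. The ERF table is defined for the ResNet50 spatial stack;
ResNet101 ledgers are produced but have no printed reference. The max
reduction is per-batch. The simulator's motion-free assumption is the
biggest gap to real recordings.
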