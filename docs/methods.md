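# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `macnet`. It is written for a reader who wants to know
exactly what the package computes and what its tests do and do not show.

## The decoding problem

Four lower-limb motor-imagery (MI) tasks — sit-to-stand (S-ST), stand-to-sit
(ST-S), walking, and standing — are decoded from 64-channel EEG recorded at
1000 Hz under a cued-trial protocol (sessions of balanced trials, 5 s MI
epochs). During MI of movement, the sensorimotor mu rhythm (7–13 Hz)
desynchronizes: its band power drops relative to the standing baseline
(event-related desynchronization, ERD). The classifier's job is to read
those spatio-spectral power patterns from 1 s windows of preprocessed EEG.

## Preprocessing

Raw recordings are turned into model-ready samples by, in order:

1. **Epoch extraction**: window [0.5 s, 5.5 s) after each event marker;
   5000 points per epoch at 1000 Hz. Indices are 0-based, windows half-open.
2. **EOG removal and linked-mastoid re-referencing**: the EOG channel is
   dropped; the mean of M1 and M2 is subtracted from every channel, and the
   mastoids themselves are then dropped, leaving 61 channels.
3. **Band-pass**: 5th-order Butterworth, 7–31 Hz, applied forward–backward
   (`sosfiltfilt`), so the effective magnitude response is |H(f)|² and the
   phase is zero. Only the design order of the filter is pinned; the
   zero-phase choice is standard for offline epoch analysis and avoids
   group-delay misalignment between channels.
4. **Downsampling** to 250 Hz by plain decimation (every 4th sample). The
   31 Hz low-pass in step 3 makes this alias-safe; polyphase resampling is
   available as `method="poly"`.
5. **Sliding-window augmentation**: each 1250-point trial is cut into five
   nonoverlapping 61 × 250 windows that inherit the trial label. Lineage
   (subject, session, trial, window) is carried with every sample.
6. **Min–max normalization** per sample over the whole 61 × 250 array:
   x̃ = (x − min x)/(max x − min x). Constant samples map to zeros rather
   than raising, keeping batch pipelines total. A per-channel scope is
   available as a flag; the whole-array scope is the default because the
   normalization formula is written with a single scalar min/max.

## Model

The full model (branch II) is, for one 61 × 250 sample:

* **Temporal refining** — single-head self-attention over the 250 time
  points, with the 61 electrodes as token embedding. Bias-free projections
  Q = XᵀW_Qᵀ, K = XᵀW_Kᵀ, V = XᵀW_Vᵀ; A = rowsoftmax(QKᵀ/√d), d = 61;
  the refined signal (AV)ᵀ is added residually. There is no positional
  encoding: time order enters only through A. The learnable value
  projection is the default because it is required to match the published
  parameter budget (111.92 K); `value_projection=False` gives the literal
  "V is the input" variant (111.61 K… minus one 61×61 matrix).
* **Temporal convolution** — 40 filters, kernel (1, 25), valid, stride 1:
  250 → 226 time points.
* **CBAM** — channel gate (global avg/max pooling → shared 2-layer MLP with
  hidden width 40/16 = 2 → sigmoid), then spatial gate (feature-map avg/max
  → 7×7 same-padded conv → sigmoid), applied multiplicatively, plus a skip
  connection: out = F + Ms(F′)⊗F′ with F′ = Mc(F)⊗F.
* **Spatial convolution** — 40 filters of shape (61, 1), collapsing the
  electrode axis.
* **Head** — affine-free batch normalization → elementwise square → average
  pooling (1, 75) stride (1, 15) (226 → 11) → safe log → dropout p = 0.3 →
  classifying convolution 4 × (1, 11) → softmax. Training minimizes mean
  cross-entropy.

Branch 0 omits both attention modules (this is the shallow-ConvNet
backbone); branch I adds only the temporal refinement.

Design choices where the published description is ambiguous:

* **Square before pooling** (default on). The layer listing gives
  BN → pool → log with no activation, but log of signed BN outputs destroys
  information; the shallow-ConvNet lineage this architecture cites uses
  square → mean-pool → log, which turns the head into a band-power
  estimator. `square_before_pool=False` gives the literal reading (with the
  log clamp warning when pooled values go non-positive).
* **Safe log before dropout** (default). Reading the prose order literally
  (pool → dropout → log) makes every dropped pooled value a log(ε) = −13.8
  outlier; the softmax saturates and early training stalls. The same
  lineage applies dropout after the log, where a dropped feature is a
  neutral 0. `dropout_before_log=True` restores the literal order.
* **Affine-free batch normalization**: required to reproduce the published
  100.44 K backbone count exactly (1040 + 97 640 + 1764 = 100 444); with
  affine BN the count would be 100.52 K. `bn_affine=True` is available.
* **Safe log**: log(max(x, ε)), ε = 1e-6; the gradient is zero on the
  clamped region.
* **Initialization**: Glorot-uniform, seeded; biases zero.
* The classifier kernel spans whatever map remains, which is (1, 11) for
  the default geometry; module-removal variants (no temporal / no spatial
  convolution) therefore stay well-formed.

Parameter budgets implied by these choices: branch II 111 908 (40×25+40
temporal, 3×61² attention, 202 + 99 CBAM, 40×40×61+40 spatial, 4×440+4
classifier), branch 0 100 444. The corresponding published figures are
111.92 K and 100.44 K.

### Numerical stack

The network, reverse-mode autodiff, Adam, cosine annealing and EMA are
implemented on NumPy (`macnet.nn`): convolutions are lowered to
im2col + GEMM (with a tap-loop path for small kernels), and every backward
rule is verified against central differences in the test suite. Training
runs in float32; correctness tests run the identical code in float64.

## Training and evaluation

* Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e-4 by default, cosine-annealed
  to zero over the run (no restarts), batch size 64, cross-entropy loss.
* An EMA shadow of all parameters is updated every step and used for
  evaluation. The effective decay warms up as min(decay, (1+t)/(10+t))
  (the TensorFlow convention) so that short runs evaluate a trained model
  rather than the random initialization; on long runs it converges to the
  configured 0.999.
* Tenfold cross-validation partitions **trials**, not samples, by default:
  the five windows of one trial are near-duplicates, and splitting them
  across folds leaks. `split_mode="sample"` mirrors the laxer protocol.
* Metrics: accuracy (%), Cohen's kappa κ = (P₀ − Pₑ)/(1 − Pₑ) from the
  confusion matrix, and a two-sided Wilcoxon signed-rank test (exact null
  for n ≤ 25, zero differences dropped) for paired model comparisons.

## Synthetic data

Real recordings for this task are not redistributable, so the package ships
a generator whose defaults emulate the acquisition protocol: 64 channels of
the 10-20 montage (including M1/M2 and EOG) at 1000 Hz, sessions of 60
balanced four-class trials, 5 s MI epochs separated by 5 s gaps.

* **Background**: Gaussian 1/f noise (exponent 1, sd 10 µV) per channel,
  synthesized in the frequency domain.
* **Mu rhythm**: band-limited Gaussian noise, flat within 7–13 Hz, on the
  ten sensorimotor channels (Cz, C1–C4, FCz, FC1/2, CP1/2). A stochastic
  narrowband process — not a pure sinusoid — is the physiologically
  standard description of an ongoing rhythm, and it means successive 1 s
  windows of a trial are essentially independent draws of the same band
  power rather than sharing a frequency/phase fingerprint a classifier
  could memorize.
* **ERD**: during the MI window the mu amplitude is scaled by
  (1 − erd_depth) on a class-specific subset of the motor set — walking:
  all motor channels; S-ST: central + anterior (FC·); ST-S: central +
  posterior (CP·); standing: none. Distinct topographies are what makes
  the three movement classes mutually separable, as the near-ceiling
  decoding reported for the real data implies; amplitude scaling makes the
  expected walking/standing band-power ratio exactly (1 − erd_depth)².
  Per-trial amplitude jitter (sd 5%) adds trial variability.
* **EOG**: 0.5–2 Hz half-sine blink artifacts on the EOG channel only
  (preprocessing drops that channel).
* **SNR**: mu variance / background variance per motor channel; default 2.
  The real recordings' SNR is uncharacterized, so this knob is a modeling
  choice, not a calibration.

What the generator does **not** emulate: volume conduction / spatial
leakage (off by default so the band-power oracles stay exact; a uniform
mixing flag exists), non-stationary artifacts other than blinks, ERD time
courses within the epoch, and inter-subject variability. Tests passing on
this generator therefore demonstrate that the pipeline and model recover
planted spatio-spectral structure — not that the architecture reaches any
particular accuracy on real EEG.

## Experiments

* **Ablation**: branches 0/I/II trained under identical seeds and splits.
* **Channel reduction**: nested subsets ordered center-out from Cz using
  standard 10-05 scalp coordinates (the published subsets are not
  enumerated; this nesting is the package's choice and is configurable).
* **Module removal**: backbone without temporal or without spatial
  convolution; the classifier kernel adapts to the remaining map.
* **Complexity audit**: parameters counted from the instantiated arrays;
  multiply–accumulates counted layer-analytically per sample
  (convolutions: output elements × kernel taps × input maps; attention
  score/value products included; softmax, sigmoid gating and elementwise
  products excluded). Published FLOP tables for such models are
  counter-convention-dependent — the figure there matches a module-level
  counter that does not see raw matmul calls — so MACs are reported, not
  asserted. Inference latency is measured (batch 64, mean over runs) and
  likewise only reported.
* **Topography**: Welch PSD (1 s Hann segments, 50% overlap) per channel,
  integrated over 7–13 Hz, averaged per condition; difference maps are
  taken against standing. On synthetic data every motor channel of a
  movement class shows a negative difference and non-motor channels show
  none — the qualitative ERD pattern.

## Desk-scale test sizes

The test suite must run on one CPU in minutes, so the statistical tests run
the full protocol at reduced size: the recovery test uses 96 trials
(2 sessions × 48) at SNR 10, 3-fold trial-level cross-validation, short
cosine-annealed runs at learning rate 1e-3 and batch 32 (the learning rate
is raised as the schedule is shortened so the total parameter displacement
stays comparable to a long 1e-4 run), and a single seed. The generator
invariance tests similarly use tens of trials and a few seeds. These sizes
are stated here so results are reproducible as printed; they are scale
choices, not new conditions — thresholds and all other parameters are the
protocol defaults.

## Known limitations

* The NumPy engine is single-threaded BLAS-bound; training beyond a few
  thousand samples is slow compared to a GPU framework.
* The generator's class topographies are a modeling invention constrained
  only by the qualitative ERD direction; absolute accuracies on it do not
  transfer to real data.
* Wilcoxon p-values with < 6 pairs cannot fall below 2/2ⁿ; significance
  claims at desk scale are illustrative.
* EDF support is import-only.
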