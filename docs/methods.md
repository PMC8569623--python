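# Methods

This note documents the models, algorithms and design choices implemented in
`semg`, in the order data flows through the package.

## Problem setting

Dynamic hand gestures are decoded from a 16-channel surface-EMG (sEMG) cuff
sampled at 1000 Hz together with a 3-axis accelerometer (ACC) worn on the
back of the hand. A trial alternates rest and sustained gesture activity
(nominally 10 s + 10 s). Six gesture classes are distinguished. The package
implements the complete decoding chain: signal conditioning, active-segment
extraction, window/feature-image construction, and a multi-stream residual
convolutional-recurrent classifier (MResLSTM) with optional ACC fusion.

## Synthetic recordings

No public dataset exists for this acquisition protocol, so the package ships
a generator whose output has the statistical structure the pipeline relies
on. Per recording:

* **EMG-like activity** — white Gaussian noise bandpass-filtered to
  20–450 Hz (the standard surface-EMG energy band; a 4th-order Butterworth
  applied forward–backward). Baseline instrumentation noise at RMS
  `baseline_rms` (default 0.02 mV-scale arbitrary units — the protocol
  never states amplitude units, so the scale is nominal) is present
  throughout.
* **Activation envelope** — zero during rest, raised-cosine 100 ms ramps
  into a plateau of 1 during the gesture. The ramps avoid discontinuities
  that would trivialize onset detection. `snr_db` sets the channel-average
  action-to-rest power ratio (default 15 dB; `-inf` disables activation).
* **Gesture signature** — a fixed per-class channel-gain vector (seeded
  log-normal, σ=0.6, normalized to unit mean square) modulates the action
  component: a spatial muscle-activation pattern without modelling
  physiology. Each class also has a fixed unit ACC direction; the ACC trace
  is the low-passed envelope along that direction (~0.5 g peak, ±15%
  per-trial amplitude jitter) plus 0.02 g sensor noise.
* **Interference** — a 50 Hz line component with 2nd and 3rd harmonics
  (amplitudes ∝ 1/k), fundamental RMS `line_amp × baseline_rms`
  (default 0.5), random phase per channel.

What this emulates: spatially structured, band-limited, amplitude-modulated
multichannel activity with line interference and gesture-correlated
kinematics. What it does not: motor-unit action potentials, electrode shift,
fatigue, inter-subject variability, or temporal microstructure within a
gesture. Tests passing on this generator therefore demonstrate that the
pipeline recovers the structure it assumes — not performance on real sEMG.

Determinism: every stream of randomness derives from `NoiseConfig.seed` via
`SeedSequence`; `signature_seed` pins class signatures independently of
per-recording noise so train and test sets share the same classes.

## Signal conditioning

**Active segments.** The multichannel energy trace
S(n) = Σ_c (x_c(n) − μ_c)², with μ_c the channel's resting mean (taken from
labelled rest spans when available, else the first 0.5 s), is smoothed with
a 64 ms moving average — raw squared sums are too jittery for run
extraction. Samples where the smoothed trace exceeds 15% of its peak form
candidate runs; runs shorter than 100 ms are discarded. Because a
peak-relative threshold alone cannot distinguish a flat noise trace from
genuine activity, the peak must additionally exceed 8× the lower-quartile
smoothed energy. That factor was placed between the measured extremes of
denoised rest-only traces (ratios ≲ 6) and action recordings at ≥ 8 dB
(ratios ≳ 14). Segments are half-open `[start, end)`, 0-based.

**Power-line removal.** An IIR notching comb at 50 Hz and harmonics. At the
native 1000 Hz rate the comb has order fs/f0 = 20 and places a notch at
every multiple of 50 Hz up to Nyquist; for sampling rates not divisible by
f0 a cascade of individual notch filters is used. Quality factor Q = 35
(≈1.4 Hz notch width) keeps mid-band content within 3 dB. Filtering is
forward–backward (zero phase) so segment boundaries are not shifted.

**Wavelet denoising.** Per channel: discrete wavelet decomposition (coif5,
depth min(5, maximum admissible), periodization mode), hard thresholding of
detail coefficients, reconstruction. Periodization makes the transform
orthogonal, so thresholding is idempotent and the no-threshold round trip is
exact to machine precision. The threshold per level is σ·SURE(d/σ) where σ
is the robust noise scale MAD/0.6745 of the finest detail band and SURE is
the Stein-unbiased-risk ("rigrsure") minimizer. `threshold_override` fixes
λ explicitly (0 disables thresholding).

## Windows, features, patches

Conditioned signals are cut into 200 ms windows with 100 ms stride — the
usual myocontrol latency budget; the protocol itself states no window
length. A window is either used directly as a channels × samples "sEMG
image", or summarized per channel by four features stacked into a 4 × C
feature image:

* MAV = (1/K) Σ|x_i|
* FR = Σ_{low band} P_i / Σ_{high band} P_i with default bands 20–45 Hz and
  95–450 Hz (the cut-offs are unstated upstream; the defaults skip the
  50 Hz notch region and are config keys). A zero high band returns a +inf
  sentinel with a warning — batch extraction must not abort — which the
  normalizer later maps to the largest finite normalized training value.
* MDF = the first frequency at which cumulative spectral power reaches half
  the total (discrete grid, no interpolation — deterministic tie-break).
* MNP = mean of the power spectrum.

Spectra are one-sided boxcar periodograms scaled so the spectrum sums to
the time-domain mean square (Parseval-consistent), making band sums power
fractions. Feature rows are z-normalized with statistics fit on the
training split only.

Each recording contributes a fixed-length sequence (default 6–8 windows)
from its longest active segment, padded by repeating the last window;
fixed-shape sequences keep batching simple. Mutual-information recursive
feature elimination ranks feature columns by plug-in MI against the labels
(16-bin quantile discretization, bits); the lowest-MI column is dropped
repeatedly, ties broken by column index, constants have MI 0.

## The network

Each window image is decomposed into n equal patches along its last axis
(time for raw images, channels for feature images; n = 4 by default) and
each patch is processed by its own stream:

* **Stream** = stem convolution (3×3; for wide raw windows a strided wide
  kernel, e.g. 3×9 stride (1,4) — strided convolution rather than pooling,
  because raw sEMG is zero-mean and plain time-axis averaging cancels the
  amplitude structure) followed by two **Re-SE units**.
* **Re-SE unit** = residual block `y = shortcut(x) + SE(F(x))` with
  F = grouped 1×1 conv → channel shuffle → 3×3 conv → BN → ReLU → grouped
  1×1 conv → BN. The SE (squeeze-and-excitation) module computes per-channel
  means (global average pooling), passes them through a two-layer
  bottleneck MLP (compression ratio k = 4, hidden width ⌈N/k⌉, minimum 1)
  and rescales the branch channels by sigmoid gates in (0,1). The last BN
  scale is zero-initialized so each block starts as an identity map.
  Grouped 1×1 convolutions (g = 2) cut pointwise parameters by g; the
  shuffle (reshape (g, N/g) → transpose → flatten) restores cross-group
  information flow.
* **Fusion** = channel-wise concatenation of stream outputs, a channel
  shuffle across streams, then a grouped 1×1 convolution + BN + ReLU.
  Without the shuffle each fused channel would see only one stream —
  concatenation order makes the stream index the group index — so the
  shuffle is what makes the grouped fusion an actual fusion.
* **Temporal integration** = a Variant ConvLSTM over the window sequence.
  The standard ConvLSTM computes all gates and the candidate with
  convolutions; the variant keeps the convolution only on the candidate
  path and computes the forget/input/output gates from globally pooled
  per-channel descriptors through fully connected maps, broadcasting the
  per-channel gate scalars over space. For input channels C_x, hidden C_h,
  kernel k this reduces parameters from 4k²(C_x+C_h)C_h + 4C_h to
  3(C_x+C_h)C_h + 3C_h + k²(C_x+C_h)C_h + C_h (about 66% fewer at
  C_x=C_h=32, k=3). Both cells give the input gate its own bias. The
  input-side terms of all time steps are computed in one batched pass;
  only the hidden-state path iterates.
* **ACC branch** = two fully connected layers on per-window ACC summary
  statistics (mean, RMS, range per axis = 9 values, averaged over the
  sequence), concatenated with the pooled LSTM state. The upstream
  description of this branch is a block diagram only; the two-FC summary
  head is this package's concrete choice.
* **Head** = FC → BN → ReLU → 50% dropout → FC → softmax.

Training: Adam (lr 1e-3 default, cosine decay), cross-entropy, batch 128,
200 epochs in the full protocol; desk-scale profiles (tests, the ablation
suite, the acceptance script) use reduced widths (8, 16), 16 hidden LSTM
channels, 12–30 epochs and 20–120 recordings per class so a full run fits
in CPU minutes. Weight init is Kaiming-uniform; all randomness (init,
shuffling, dropout, validation split) derives from the training seed.
Floating point is float64 throughout — the engine favours testability over
speed.

## The four-configuration comparison

`run_ablation` trains, on identical data per seed: (1) the plain
single-network baseline — one stream over the whole raw image and no
recurrent temporal stage (`use_lstm=False`; window features are averaged
over time), (2) the multi-stream network on raw images, (3) multi-stream
raw + ACC, (4) multi-stream feature images + ACC; test accuracies are
tabulated over 3 seeds. Experiment 1 is deliberately a *different, simpler
model*, not the full architecture with one stream: the comparison contrasts
the proposed machinery against a conventional single CNN. (Measured on this
generator, a one-stream variant of the full architecture is not inferior to
the multi-stream one — the class signal is global across the window, so
patch decomposition alone buys little here; the informative differences
come from the temporal-fusion stage, the ACC branch, and the feature
images.) The default desk-scale suite uses 20 train / 15 test recordings
per class at 12 dB, 1.6 s trials, 5-window sequences and 15 epochs.

## Numerical / degenerate-input choices

* Window counts: ⌊(T−L)/S⌋+1, trailing remainder dropped; a window longer
  than the signal is an error.
* Patch decomposition requires divisibility and reports the needed padding.
* Empty spectra: MDF raises; FR returns the +inf sentinel; MNP of an empty
  array raises.
* Recall of a class absent from a test split is NaN, never 0.
* NaN training loss aborts with a diagnostic rather than continuing.
* Checkpoints are single-file `.npz` archives with the config embedded as
  JSON.

## Known limitations

* The autodiff engine is minimal and single-threaded; it is written for
  correctness (gradient-checked) at desk scale, not for large-scale
  training.
* The generator's class structure is spatial (channel gains); architectures
  whose advantage lies in temporal microstructure cannot show it here.
* The 52-class benchmark-style head is exercised for its forward contracts
  only; no external data is downloaded or trained on.
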