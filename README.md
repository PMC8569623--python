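# semg-mreslstm

Dynamic hand-gesture recognition from multichannel surface electromyography
(sEMG), for researchers building myoelectric control pipelines: prosthetics
and manipulator control, movement decoding, and biosignal classification
benchmarks.

A 16-channel sEMG cuff plus a 3-axis accelerometer (ACC) record trials that
alternate rest and one of six sustained dynamic gestures. The package
implements the full decoding chain:

1. **Conditioning** — active-segment detection on the multichannel energy
   S(n) = Σ_c (x_c(n) − μ_c)² with a 15%-of-peak threshold; a 20th-order
   IIR notching comb at 50 Hz and harmonics; wavelet denoising (coif5,
   SURE thresholds, hard thresholding).
2. **Imaging** — sliding windows (200 ms / 100 ms) as channels × samples
   sEMG images, or 4 × C feature images of per-channel MAV, FR, MDF, MNP;
   mutual-information recursive feature elimination.
3. **MResLSTM** — each window image is decomposed into n equal patches;
   each patch feeds its own stream of Re-SE residual units
   (squeeze-and-excitation gating, channel-shuffled grouped pointwise
   convolutions); stream outputs are fused and integrated over time by a
   **Variant ConvLSTM** whose gates act on globally pooled per-channel
   descriptors (f_t = σ(W_fh·GP(H_{t−1}) + W_fx·GP(X_t) + b_f), only the
   candidate path stays convolutional), cutting the recurrent parameter
   count by about two thirds; an optional ACC branch joins before the
   softmax head.

Because no public dataset exists for this acquisition protocol, a
first-class synthetic generator (`semg.synthetic`) emulates it: bandlimited
EMG-like noise shaped by per-class channel-gain signatures and
raised-cosine activation envelopes, 50 Hz interference with harmonics, and
gesture-correlated ACC trajectories. The network and its training loop run
on a small, gradient-checked numpy autodiff engine — no GPU or deep-learning
framework required.

## Worked example

```python
from semg import (NoiseConfig, generate_dataset, PipelineConfig,
                  build_arrays, GestureClassifier, ModelConfig, TrainConfig)

cfg = NoiseConfig(snr_db=15.0, seed=7)
train_recs, test_recs = generate_dataset(30, 10, 6, fs=1000.0, cfg=cfg,
                                         duration_s=2.0)

pipe = PipelineConfig(mode="feature", n_windows=6)
train, norm = build_arrays(train_recs, pipe, fit_normalizer=True)
test, _ = build_arrays(test_recs, pipe, normalizer=norm)

model_cfg = ModelConfig(n_classes=6, streams=4, input_mode="feature",
                        in_height=4, in_width=16, widths=(8, 16),
                        lstm_hidden=16, fc_hidden=32, use_acc=True)
clf = GestureClassifier(train, model_cfg)
res = clf.fit(TrainConfig(batch_size=64, epochs=15, lr=2e-3, seed=0))
print(res.summary())
print("test accuracy:", res.evaluate(test).accuracy)
```

Output:

```
               quantity    value
0            input mode  feature
1               streams        4
2        use ACC branch     True
3  trainable parameters    22798
4                epochs       15
5            batch size       64
6      final train loss   0.5656
7     best val accuracy      1.0
test accuracy: 0.95
```

180 recordings (6 gestures × 30) at 15 dB action-to-rest SNR already carry
enough structure for the feature-image + ACC configuration to reach 95%
test accuracy in 15 epochs (and ≥ 90% at the larger 120-per-class protocol
of the acceptance script); the interesting regimes (lower SNR, raw-image
input, no ACC) are explored by the ablation suite:

```bash
semg ablation --out ablation.csv     # four configurations, three seeds
```

The CLI also exposes each stage (`semg simulate`, `semg preprocess`,
`semg featurize`, `semg train`, `semg evaluate`,
`semg model summary`).

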