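"""Recording-to-array pipeline: conditioning, windowing, feature images,
and accelerometer summary features, assembled into fixed-shape batches.

Each recording contributes one training sample: a fixed-length sequence of
window images cut from its active segment (padded by repeating the last
window when the segment is short) plus per-window ACC summary statistics
(mean, RMS, range per axis). Feature normalization statistics are fit on
the training split only and reused for test data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyInputError
from .features import (BandConfig, FeatureNormalizer, build_feature_image,
                       window_signal)
from .preprocess import DenoiseConfig, preprocess_recording
from .synthetic import Recording

__all__ = ["ArrayDataset", "PipelineConfig", "recording_to_sequence",
           "build_arrays"]


@dataclass(frozen=True)
class PipelineConfig:
    """Windowing and conditioning choices shared by train and test."""
    mode: str = "raw"                 # "raw" | "feature"
    window_ms: float = 200.0
    stride_ms: float = 100.0
    n_windows: int = 8
    do_preprocess: bool = True
    th_fraction: float = 0.15
    band: BandConfig = BandConfig()
    denoise: DenoiseConfig = DenoiseConfig()


@dataclass
class ArrayDataset:
    """Stacked network inputs: X [N,T,H,W], acc [N,T,9], labels y [N]."""
    X: np.ndarray
    acc: np.ndarray
    y: np.ndarray
    mode: str

    def __len__(self) -> int:
        return self.X.shape[0]


def _acc_window_features(acc: np.ndarray) -> np.ndarray:
    """Mean, RMS and range per axis of one ACC window -> 9 values."""
    mean = acc.mean(axis=1)
    rms = np.sqrt(np.mean(acc ** 2, axis=1))
    rng = acc.max(axis=1) - acc.min(axis=1)
    return np.concatenate([mean, rms, rng])


def recording_to_sequence(rec: Recording, cfg: PipelineConfig,
                          normalizer: FeatureNormalizer | None = None):
    """One recording -> (window images [T,H,W], ACC features [T,9]).

    The longest detected active segment supplies the windows; a recording
    with no detectable activity falls back to its trailing half. In feature
    mode the returned images are unnormalized unless a fitted normalizer is
    supplied.
    """
    fs = rec.fs
    if cfg.do_preprocess:
        clean, segs = preprocess_recording(rec, denoise=cfg.denoise,
                                           th_fraction=cfg.th_fraction)
    else:
        from .preprocess import detect_active_segments
        clean, segs = rec, detect_active_segments(rec, th_fraction=cfg.th_fraction)

    if segs:
        seg = max(segs, key=lambda s: s.length)
        a, b = seg.start, seg.end
    else:
        a, b = rec.n_samples // 2, rec.n_samples

    L = int(round(cfg.window_ms * 1e-3 * fs))
    S = int(round(cfg.stride_ms * 1e-3 * fs))
    if b - a < L:                      # widen a too-short segment
        a = max(0, b - L)
    emg_wins = window_signal(clean.semg[:, a:b], L, S)[:cfg.n_windows]
    acc_wins = window_signal(rec.acc[:, a:b], L, S)[:cfg.n_windows]
    while len(emg_wins) < cfg.n_windows:
        emg_wins.append(emg_wins[-1])
        acc_wins.append(acc_wins[-1])

    if cfg.mode == "feature":
        imgs = [build_feature_image(w, fs, cfg.band, normalizer).values
                for w in emg_wins]
    else:
        imgs = [w.pixels for w in emg_wins]
    acc_feats = [_acc_window_features(w.pixels) for w in acc_wins]
    return np.stack(imgs), np.stack(acc_feats)


def build_arrays(recordings: list[Recording], cfg: PipelineConfig,
                 normalizer: FeatureNormalizer | None = None,
                 fit_normalizer: bool = False):
    """Stack a recording collection into an ArrayDataset.

    Feature mode: pass ``fit_normalizer=True`` for the training split (the
    fitted normalizer is returned for reuse), or a fitted ``normalizer``
    for the test split. Returns (dataset, normalizer).
    """
    if not recordings:
        raise EmptyInputError("no recordings given")
    Xs, As, ys = [], [], []
    for rec in recordings:
        x, a = recording_to_sequence(rec, cfg, normalizer=None)
        Xs.append(x)
        As.append(a)
        ys.append(rec.label if isinstance(rec.label, (int, np.integer)) else -1)
    X = np.stack(Xs)
    acc = np.stack(As)
    y = np.asarray(ys, dtype=np.int64)

    if cfg.mode == "feature":
        from .features import FeatureImage
        if fit_normalizer:
            normalizer = FeatureNormalizer().fit(
                [FeatureImage(img) for sample in Xs for img in sample])
        if normalizer is None:
            raise EmptyInputError(
                "feature mode needs a fitted normalizer (or fit_normalizer=True)")
        N, T = X.shape[:2]
        flat = X.reshape(N * T, *X.shape[2:])
        X = np.stack([normalizer.transform(FeatureImage(img)).values
                      for img in flat]).reshape(X.shape)
    return ArrayDataset(X=X, acc=acc, y=y, mode=cfg.mode), normalizer
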