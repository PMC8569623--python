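"""Synthetic multichannel sEMG + accelerometer recordings.

The study protocol this emulates: a 16-channel surface-EMG cuff sampled at
1000 Hz plus a 3-axis accelerometer on the back of the hand, recording
cycles of 10 s rest followed by 10 s of one of six dynamic hand gestures.
Since no public recording of that protocol exists, this module generates
signals with the statistical structure the downstream pipeline relies on:

* EMG-like activity = white Gaussian noise bandpass-filtered to the 20-450 Hz
  surface-EMG energy band, amplitude-modulated by a smooth activation
  envelope (raised-cosine 100 ms ramps into a plateau);
* a fixed per-class channel-gain vector (a seeded random spatial pattern
  standing in for muscle-specific activation) plus a class-specific
  accelerometer direction;
* 50 Hz power-line interference with decaying harmonics, and baseline
  instrumentation noise present throughout.

Amplitudes are millivolt-scale arbitrary units. The generator is fully
deterministic given the seed in :class:`NoiseConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError

__all__ = ["NoiseConfig", "Recording", "GESTURE_NAMES",
           "generate_recording", "generate_dataset"]

# Six dynamic gestures: two-finger left/right turn, flat-palm flip,
# flat-palm left/right turn, flat-palm fist. (The source protocol's
# abbreviations collide for two of them; ids 0-5 are authoritative here.)
GESTURE_NAMES = ["TFTR", "TFTL", "FPFL", "FPTL", "FPTR", "FPMF"]


@dataclass(frozen=True)
class NoiseConfig:
    """Noise and activation parameters of the generator.

    snr_db is the action-to-rest power ratio in dB (channel average);
    ``-inf`` disables activation entirely. line_amp is the RMS of the 50 Hz
    fundamental relative to baseline_rms. signature_seed pins the per-class
    gain patterns independently of the per-recording noise seed; it defaults
    to ``seed`` so a single config is self-contained.
    """
    emg_band: tuple[float, float] = (20.0, 450.0)
    line_freq: float = 50.0
    line_amp: float = 0.5
    baseline_rms: float = 0.02
    snr_db: float = 15.0
    seed: int = 0
    signature_seed: int | None = None

    def validate(self, fs: float) -> None:
        lo, hi = self.emg_band
        if not (0.0 < lo < hi < fs / 2):
            raise ConfigurationError(
                f"emg_band {self.emg_band} must satisfy 0 < low < high < fs/2={fs / 2}")
        if self.line_amp < 0:
            raise ConfigurationError("line_amp must be >= 0")
        if self.baseline_rms <= 0:
            raise ConfigurationError("baseline_rms must be > 0")


@dataclass
class Recording:
    """One labeled trial: sEMG [C,T], accelerometer [3,T], metadata."""
    semg: np.ndarray
    acc: np.ndarray
    fs: float
    label: int | str
    subject: str = "S0"
    envelope: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.semg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.semg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _class_signature(gesture: int, n_channels: int, sig_seed: int):
    """Per-class channel gains (mean-square 1) and unit ACC direction."""
    rng = np.random.default_rng(np.random.SeedSequence([sig_seed, 0xC1A5, gesture]))
    g = rng.lognormal(mean=0.0, sigma=0.6, size=n_channels)
    g /= np.sqrt(np.mean(g ** 2))
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    return g, d


def _bandlimited_noise(rng, n, fs, band):
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _envelope(t: np.ndarray, rest_s: float, action_s: float, ramp_s: float):
    """0 during rest, raised-cosine 100 ms ramps into a plateau of 1."""
    env = np.zeros_like(t)
    t0, t1 = rest_s, rest_s + action_s
    up = (t >= t0) & (t < t0 + ramp_s)
    env[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - t0) / ramp_s))
    plateau = (t >= t0 + ramp_s) & (t < t1 - ramp_s)
    env[plateau] = 1.0
    down = (t >= t1 - ramp_s) & (t < t1)
    env[down] = 0.5 * (1 - np.cos(np.pi * (t1 - t[down]) / ramp_s))
    return env


def generate_recording(gesture: int, duration_s: float, fs: float,
                       cfg: NoiseConfig, n_channels: int = 16,
                       rest_fraction: float = 0.5, ramp_s: float = 0.1,
                       subject: str = "S0") -> Recording:
    """Generate one rest-then-action trial for ``gesture``.

    The first ``rest_fraction`` of the trial is rest, the remainder the
    sustained gesture (default mirrors the 10 s + 10 s acquisition cycle).
    Bit-identical output for identical arguments.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be > 0")
    if not 0 <= gesture < len(GESTURE_NAMES):
        raise ConfigurationError(f"gesture id {gesture} outside 0..{len(GESTURE_NAMES)-1}")
    cfg.validate(fs)

    T = int(round(duration_s * fs))
    t = np.arange(T) / fs
    sig_seed = cfg.seed if cfg.signature_seed is None else cfg.signature_seed
    gains, acc_dir = _class_signature(gesture, n_channels, sig_seed)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, gesture]))

    rest_s = duration_s * rest_fraction
    action_s = duration_s - rest_s
    active = np.isfinite(cfg.snr_db)
    env = (_envelope(t, rest_s, action_s, min(ramp_s, action_s / 2))
           if active else np.zeros(T))

    semg = np.empty((n_channels, T))
    action_rms = cfg.baseline_rms * 10 ** (cfg.snr_db / 20.0) if active else 0.0
    for c in range(n_channels):
        base = _bandlimited_noise(rng, T, fs, cfg.emg_band) * cfg.baseline_rms
        x = base
        if active:
            burst = _bandlimited_noise(rng, T, fs, cfg.emg_band)
            x = x + burst * env * (action_rms * gains[c])
        if cfg.line_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            for k in (1, 2, 3):
                amp = np.sqrt(2.0) * cfg.line_amp * cfg.baseline_rms / k
                x = x + amp * np.sin(2 * np.pi * k * cfg.line_freq * t + phase)
        semg[c] = x

    # smooth gesture-correlated kinematics: low-passed envelope along a
    # class-specific direction, ~0.5 g peak, plus sensor noise
    if active and env.max() > 0:
        sos = signal.butter(2, 5.0, btype="lowpass", fs=fs, output="sos")
        traj = signal.sosfiltfilt(sos, env)
    else:
        traj = np.zeros(T)
    amp_jitter = rng.uniform(0.85, 1.15)
    acc = 0.5 * amp_jitter * acc_dir[:, None] * traj[None, :]
    acc = acc + 0.02 * rng.standard_normal((3, T))

    return Recording(semg=semg, acc=acc, fs=fs,
                     label=gesture if active else "rest",
                     subject=subject, envelope=env)


def generate_dataset(n_train_per_class: int, n_test_per_class: int,
                     n_classes: int, fs: float, cfg: NoiseConfig,
                     duration_s: float = 20.0, n_channels: int = 16,
                     **kwargs) -> tuple[list[Recording], list[Recording]]:
    """Class-balanced disjoint train/test recording collections.

    Per-recording seeds are derived deterministically from ``cfg.seed``;
    the per-class gain signatures are shared across the whole dataset.
    """
    if n_train_per_class < 1 or n_test_per_class < 1:
        raise ConfigurationError("per-class counts must be >= 1")
    if n_classes < 2:
        raise ConfigurationError("need at least 2 classes")
    if n_classes > len(GESTURE_NAMES):
        raise ConfigurationError(f"at most {len(GESTURE_NAMES)} gesture classes")

    sig_seed = cfg.seed if cfg.signature_seed is None else cfg.signature_seed
    ss = np.random.SeedSequence(cfg.seed)
    n_total = n_train_per_class + n_test_per_class
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(n_classes * n_total)]

    train, test = [], []
    idx = 0
    for g in range(n_classes):
        for j in range(n_total):
            rc = replace(cfg, seed=child_seeds[idx], signature_seed=sig_seed)
            rec = generate_recording(g, duration_s, fs, rc,
                                     n_channels=n_channels, **kwargs)
            (train if j < n_train_per_class else test).append(rec)
            idx += 1
    return train, test
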