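"""Windowed sEMG images, handcrafted feature images, patch decomposition,
and mutual-information feature ranking.

A conditioned recording is cut into overlapping windows (default 200 ms with
100 ms stride, the usual myocontrol latency budget); each window is either
used directly as a channels-by-samples "sEMG image" or summarized per
channel by four features:

* MAV — mean absolute value, (1/K) sum |x_i|
* FR  — low-band to high-band spectral power ratio
* MDF — median frequency: first frequency where cumulative power reaches
        half of the total
* MNP — mean of the power spectrum

stacked into a 4 x C feature image. The spectral features use a one-sided
boxcar periodogram scaled so that the spectrum sums to the time-domain mean
square (Parseval-consistent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .exceptions import DimensionError, EmptyInputError

__all__ = [
    "EmgImage", "FeatureImage", "PatchSet", "BandConfig",
    "window_signal", "mean_absolute_value", "power_spectrum",
    "frequency_ratio", "median_frequency", "mean_power",
    "build_feature_image", "FeatureNormalizer",
    "decompose_patches", "reassemble_patches",
    "mutual_information", "rank_features_mutual_information",
]


@dataclass
class EmgImage:
    """One window of multichannel signal: pixels [C, L] starting at t0."""
    pixels: np.ndarray
    t0: int
    window_len: int
    stride: int


@dataclass
class FeatureImage:
    """Per-window 4 x C feature matrix, rows ordered (MAV, FR, MDF, MNP)."""
    values: np.ndarray
    feature_names: tuple[str, ...] = ("MAV", "FR", "MDF", "MNP")


@dataclass
class PatchSet:
    """Equal-size contiguous slices of an image along its last (time) axis."""
    patches: list[np.ndarray]

    @property
    def n(self) -> int:
        return len(self.patches)


@dataclass(frozen=True)
class BandConfig:
    """Cut-off frequencies (Hz) of the FR low and high bands.

    Defaults skip the 50 Hz interference region: low band 20-45 Hz, high
    band 95-450 Hz.
    """
    llc: float = 20.0
    lhc: float = 45.0
    hlc: float = 95.0
    hhc: float = 450.0

    def validate(self, fs: float) -> None:
        if not (self.llc < self.lhc <= self.hlc < self.hhc <= fs / 2):
            raise DimensionError(
                f"band edges must satisfy LLC < LHC <= HLC < HHC <= fs/2; "
                f"got {self} at fs={fs}")


def window_signal(x: np.ndarray, window_len: int, stride: int) -> list[EmgImage]:
    """Slide a [C, T] signal into ⌊(T-L)/S⌋+1 windows; remainder dropped."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    T = x.shape[-1]
    if window_len < 2:
        raise DimensionError("window_len must be >= 2")
    if stride < 1:
        raise DimensionError("stride must be >= 1")
    if window_len > T:
        raise EmptyInputError(f"window_len {window_len} exceeds signal length {T}")
    starts = range(0, T - window_len + 1, stride)
    return [EmgImage(x[:, s:s + window_len].copy(), s, window_len, stride)
            for s in starts]


def mean_absolute_value(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise EmptyInputError("MAV of empty input")
    return float(np.mean(np.abs(x)))


def power_spectrum(x: np.ndarray, fs: float):
    """One-sided periodogram of a 1-D window.

    Boxcar window, no detrending, 'spectrum' scaling: sum(P) equals the
    time-domain mean square exactly, so band sums are power fractions.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise EmptyInputError("need at least 2 samples for a spectrum")
    freqs, P = _sig.periodogram(x, fs=fs, window="boxcar", detrend=False,
                                scaling="spectrum")
    return freqs, P


def frequency_ratio(P: np.ndarray, freqs: np.ndarray,
                    band: BandConfig = BandConfig()) -> float:
    """Low-band power over high-band power; +inf sentinel on empty high band.

    Batch extraction must never abort on a degenerate spectrum, so a zero
    high-band denominator yields +inf with a warning rather than an error.
    """
    P = np.asarray(P, dtype=np.float64)
    freqs = np.asarray(freqs, dtype=np.float64)
    low = P[(freqs >= band.llc) & (freqs <= band.lhc)].sum()
    high = P[(freqs >= band.hlc) & (freqs <= band.hhc)].sum()
    if high <= 0.0:
        warnings.warn("zero high-band power; FR reported as +inf",
                      RuntimeWarning, stacklevel=2)
        return float("inf")
    return float(low / high)


def median_frequency(P: np.ndarray, freqs: np.ndarray) -> float:
    """First frequency where cumulative power reaches half the total."""
    P = np.asarray(P, dtype=np.float64)
    total = P.sum()
    if total <= 0:
        raise EmptyInputError("median frequency of an all-zero spectrum")
    idx = int(np.searchsorted(np.cumsum(P), 0.5 * total))
    return float(np.asarray(freqs)[idx])


def mean_power(P: np.ndarray) -> float:
    P = np.asarray(P, dtype=np.float64)
    if P.size == 0:
        raise EmptyInputError("mean power of empty spectrum")
    return float(P.mean())


def build_feature_image(window: EmgImage, fs: float,
                        band: BandConfig = BandConfig(),
                        normalizer: "FeatureNormalizer | None" = None) -> FeatureImage:
    """4 x C feature matrix of one window; optionally z-normalized.

    Each channel is summarized independently (no cross-channel leakage).
    """
    band.validate(fs)
    px = window.pixels
    C = px.shape[0]
    vals = np.empty((4, C))
    for c in range(C):
        x = px[c]
        freqs, P = power_spectrum(x, fs)
        vals[0, c] = mean_absolute_value(x)
        vals[1, c] = frequency_ratio(P, freqs, band)
        if P.sum() > 0:
            vals[2, c] = median_frequency(P, freqs)
        else:
            vals[2, c] = 0.0
        vals[3, c] = mean_power(P)
    img = FeatureImage(vals)
    return normalizer.transform(img) if normalizer is not None else img


class FeatureNormalizer:
    """Per-feature z-normalization with statistics fit on the training split.

    Infinite entries (the FR sentinel) are excluded from the statistics and
    mapped to the largest finite normalized training value of their feature
    row, so downstream arrays stay finite.
    """

    def __init__(self):
        self.mean_ = None
        self.std_ = None
        self.max_norm_ = None

    def fit(self, images: list[FeatureImage]) -> "FeatureNormalizer":
        if not images:
            raise EmptyInputError("cannot fit normalizer on empty image list")
        stack = np.stack([im.values for im in images])        # [N, 4, C]
        flat = stack.reshape(stack.shape[0], 4, -1)
        finite = np.isfinite(flat)
        self.mean_ = np.zeros(4)
        self.std_ = np.ones(4)
        self.max_norm_ = np.zeros(4)
        for f in range(4):
            vals = flat[:, f, :][finite[:, f, :]]
            if vals.size:
                self.mean_[f] = vals.mean()
                sd = vals.std()
                self.std_[f] = sd if sd > 0 else 1.0
                self.max_norm_[f] = np.max((vals - self.mean_[f]) / self.std_[f])
        return self

    def transform(self, img: FeatureImage) -> FeatureImage:
        if self.mean_ is None:
            raise RuntimeError("normalizer not fitted")
        z = (img.values - self.mean_[:, None]) / self.std_[:, None]
        for f in range(4):
            z[f][~np.isfinite(z[f])] = self.max_norm_[f]
        return FeatureImage(z, img.feature_names)


def decompose_patches(img: np.ndarray, n: int) -> PatchSet:
    """Split an image into n contiguous equal slices along the time axis."""
    img = np.asarray(img)
    L = img.shape[-1]
    if n < 1:
        raise DimensionError("n must be >= 1")
    if L % n:
        pad = n - (L % n)
        raise DimensionError(
            f"time axis length {L} not divisible by {n} patches; "
            f"pad by {pad} samples or choose a divisor")
    return PatchSet(list(np.split(img, n, axis=-1)))


def reassemble_patches(ps: PatchSet) -> np.ndarray:
    return np.concatenate(ps.patches, axis=-1)


# ---------------------------------------------------------------------------
# mutual-information recursive feature elimination

def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize by quantile edges; constant columns collapse to one bin."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(edges), x, side="right")


def mutual_information(x: np.ndarray, labels: np.ndarray, n_bins: int = 16) -> float:
    """Plug-in MI (bits) between a feature column and integer labels.

    Quantile discretization into ``n_bins``; a constant column has MI 0.
    """
    x = np.asarray(x, dtype=np.float64)
    labels = np.asarray(labels)
    if x.shape[0] != labels.shape[0]:
        raise DimensionError("feature column and labels differ in length")
    xb = _quantile_bins(x, n_bins)
    xs = np.unique(xb, return_inverse=True)[1]
    ys = np.unique(labels, return_inverse=True)[1]
    joint = np.zeros((xs.max() + 1, ys.max() + 1))
    np.add.at(joint, (xs, ys), 1.0)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


def rank_features_mutual_information(features: np.ndarray, labels: np.ndarray,
                                     n_select: int | None = None,
                                     n_bins: int = 16):
    """Recursive elimination by lowest MI against the labels.

    Repeatedly drops the remaining feature column with the lowest estimated
    MI (ties broken by column index). Returns (elimination_order, selected):
    the order columns were dropped in, and the indices of the ``n_select``
    survivors (default: top half).
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise DimensionError("need a [samples x F>=2] feature matrix")
    n_feat = X.shape[1]
    if len(np.unique(labels)) < 2:
        raise DimensionError("need at least 2 classes")
    if n_select is None:
        n_select = max(1, n_feat // 2)

    remaining = list(range(n_feat))
    order: list[int] = []
    while len(remaining) > n_select:
        mis = [mutual_information(X[:, j], labels, n_bins) for j in remaining]
        drop = remaining[int(np.argmin(mis))]   # argmin takes first on ties
        order.append(drop)
        remaining.remove(drop)
    # continue ranking the survivors so the full elimination order is defined
    rest = list(remaining)
    while len(rest) > 1:
        mis = [mutual_information(X[:, j], labels, n_bins) for j in rest]
        drop = rest[int(np.argmin(mis))]
        order.append(drop)
        rest.remove(drop)
    order.extend(rest)
    return order, sorted(remaining)
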