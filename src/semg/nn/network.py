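"""The multi-stream residual ConvLSTM gesture classifier (MResLSTM).

Each time window of the conditioned recording is an image (channels x
samples for raw mode, 4 features x channels for feature mode). The image is
decomposed into equal patches along its last axis; each patch is processed
by its own stream (a small stem convolution followed by two Re-SE residual
units with grouped pointwise convolutions and channel shuffle). Stream
outputs are fused by channel-wise concatenation and a grouped pointwise
convolution into a unified feature map. A Variant ConvLSTM then integrates
the fused maps across the window sequence; its final hidden state is
globally pooled, optionally concatenated with an accelerometer branch (two
fully connected layers on per-window ACC summary statistics), and classified
by a fully connected head with batch normalization, ReLU and dropout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ..exceptions import ConfigurationError, DimensionError
from .autograd import Tensor, concatenate
from .convlstm import VConvLSTMCell
from .layers import (BatchNorm, Conv2d, Dropout, Linear, Module, ReSEBlock,
                     channel_shuffle)

__all__ = ["ModelConfig", "MResLSTM", "Stream", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    in_height/in_width describe one window image before patch decomposition
    (raw mode: EMG channels x window samples; feature mode: 4 x channels).
    For wide raw windows the stem convolution can downsample with a strided
    wide kernel (``stem_kernel``/``stem_stride``); strided convolution — not
    plain pooling — because raw sEMG is zero-mean and averaging the time
    axis would cancel the very amplitude structure the network must learn.
    """
    n_classes: int = 6
    streams: int = 4
    input_mode: str = "raw"              # "raw" | "feature"
    in_height: int = 16
    in_width: int = 200
    widths: tuple[int, int] = (16, 32)
    groups: int = 2
    se_ratio: int = 4
    lstm_hidden: int = 32
    lstm_kernel: int = 3
    dropout: float = 0.5
    fc_hidden: int = 64
    use_acc: bool = False
    use_lstm: bool = True     # False: plain CNN baseline, temporal mean
    acc_features: int = 9
    acc_hidden: int = 16
    stem_kernel: tuple[int, int] = (3, 3)
    stem_stride: tuple[int, int] = (1, 1)
    block2_stride: tuple[int, int] = (1, 1)

    def __post_init__(self):
        if self.input_mode not in ("raw", "feature"):
            raise ConfigurationError(f"unknown input_mode {self.input_mode!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0,1)")
        for w in self.widths:
            if w % self.groups:
                raise ConfigurationError(
                    f"width {w} not divisible by groups={self.groups}")
        if self.in_width % self.streams:
            raise ConfigurationError(
                f"window width {self.in_width} not divisible by "
                f"{self.streams} streams")

    @property
    def patch_width(self) -> int:
        return self.in_width // self.streams


class Stream(Module):
    """One stream: stem conv + two Re-SE units on a single patch."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        w0, w1 = cfg.widths
        kh, kw = cfg.stem_kernel
        self.stem = Conv2d(1, w0, cfg.stem_kernel, rng, stride=cfg.stem_stride,
                           padding=(kh // 2, kw // 2), bias=False)
        self.stem_bn = BatchNorm(w0)
        self.block1 = ReSEBlock(w0, w0, cfg.groups, cfg.se_ratio, rng)
        self.block2 = ReSEBlock(w0, w1, cfg.groups, cfg.se_ratio, rng,
                                stride=cfg.block2_stride)

    def forward(self, x: Tensor) -> Tensor:
        h = self.stem_bn(self.stem(x)).relu()
        return self.block2(self.block1(h))

    __call__ = forward


class MResLSTM(Module):
    """Multi-stream residual network with Variant ConvLSTM temporal fusion."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E9]))
        self.streams = [Stream(cfg, rng) for _ in range(cfg.streams)]
        w1 = cfg.widths[1]
        self.fuse = Conv2d(cfg.streams * w1, cfg.lstm_hidden, 1, rng,
                           groups=cfg.streams if cfg.streams > 1 else 1, bias=False)
        self.fuse_bn = BatchNorm(cfg.lstm_hidden)
        self.lstm = (VConvLSTMCell(cfg.lstm_hidden, cfg.lstm_hidden,
                                   cfg.lstm_kernel, rng)
                     if cfg.use_lstm else None)
        head_in = cfg.lstm_hidden
        if cfg.use_acc:
            self.acc_fc1 = Linear(cfg.acc_features, cfg.acc_hidden, rng)
            self.acc_fc2 = Linear(cfg.acc_hidden, cfg.acc_hidden, rng)
            head_in += cfg.acc_hidden
        self.fc1 = Linear(head_in, cfg.fc_hidden, rng)
        self.fc_bn = BatchNorm(cfg.fc_hidden)
        self.drop = Dropout(cfg.dropout, np.random.default_rng(
            np.random.SeedSequence([seed, 0xD0])))
        self.fc2 = Linear(cfg.fc_hidden, cfg.n_classes, rng)

    # -- input plumbing ----------------------------------------------------

    def _prepare(self, emg: np.ndarray) -> list[np.ndarray]:
        """[B,T,H,W] -> per-stream patch batches [B*T,1,H,Wp] (numpy)."""
        if emg.ndim != 4:
            raise DimensionError(f"expected [batch, windows, H, W], got {emg.shape}")
        B, T, H, W = emg.shape
        cfg = self.cfg
        if (H, W) != (cfg.in_height, cfg.in_width):
            raise DimensionError(
                f"window image {H}x{W} does not match config "
                f"{cfg.in_height}x{cfg.in_width}")
        x = emg.reshape(B * T, 1, H, W)
        return np.split(x, cfg.streams, axis=-1)

    # -- forward -----------------------------------------------------------

    def forward(self, emg: np.ndarray, acc: np.ndarray | None = None) -> Tensor:
        """Class logits [B, n_classes] from windows [B,T,H,W] (+ ACC [B,T,A])."""
        cfg = self.cfg
        if cfg.use_acc and acc is None:
            raise DimensionError("model configured with use_acc but no ACC input given")
        B, T = emg.shape[:2]

        patches = self._prepare(np.asarray(emg, dtype=np.float64))
        feats = [s(Tensor(p)) for s, p in zip(self.streams, patches)]
        cat = concatenate(feats, axis=1)
        if cfg.streams > 1:
            # shuffle across streams so each fusion group mixes all streams
            cat = channel_shuffle(cat, cfg.streams)
        fused = self.fuse_bn(self.fuse(cat)).relu()

        _, Cf, Hf, Wf = fused.shape
        seq = fused.reshape(B, T, Cf, Hf, Wf)
        if cfg.use_lstm:
            H_t = self.lstm.forward_sequence(seq)
            h = H_t.mean(axis=(2, 3))                 # [B, lstm_hidden]
        else:
            h = seq.mean(axis=(1, 3, 4))              # temporal + spatial mean

        if cfg.use_acc:
            a = np.asarray(acc, dtype=np.float64)
            if a.shape[:2] != (B, T) or a.shape[2] != cfg.acc_features:
                raise DimensionError(
                    f"ACC input {a.shape} incompatible with [B={B},T={T},"
                    f"{cfg.acc_features}]")
            av = Tensor(a.mean(axis=1))
            av = self.acc_fc2(self.acc_fc1(av).relu()).relu()
            h = concatenate([h, av], axis=1)

        h = self.drop(self.fc_bn(self.fc1(h)).relu())
        return self.fc2(h)

    __call__ = forward

    def predict_proba(self, emg: np.ndarray, acc: np.ndarray | None = None,
                      batch_size: int = 64) -> np.ndarray:
        """Softmax class scores in eval mode (deterministic)."""
        was_training = self.training
        self.eval()
        outs = []
        for i in range(0, emg.shape[0], batch_size):
            sl = slice(i, i + batch_size)
            logits = self.forward(emg[sl],
                                  None if acc is None else acc[sl]).data
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            outs.append(e / e.sum(axis=1, keepdims=True))
        self.train(was_training)
        return np.concatenate(outs, axis=0)

    def predict(self, emg: np.ndarray, acc: np.ndarray | None = None) -> np.ndarray:
        return self.predict_proba(emg, acc).argmax(axis=1)

    def summary(self):
        """Per-component parameter counts as a DataFrame."""
        import pandas as pd
        rows = []
        groups: dict[str, int] = {}
        for name, p in self.named_parameters():
            top = name.split(".")[0]
            groups[top] = groups.get(top, 0) + p.data.size
        for k, v in groups.items():
            rows.append({"component": k, "parameters": v})
        rows.append({"component": "TOTAL", "parameters": self.n_parameters()})
        return pd.DataFrame(rows)


def save_checkpoint(path, model: MResLSTM) -> None:
    """Single-file archive: weights + embedded config JSON."""
    cfg_json = json.dumps(asdict(model.cfg))
    arrays = dict(model.state_dict())
    arrays["__config__"] = np.frombuffer(cfg_json.encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> MResLSTM:
    with np.load(path) as z:
        cfg_dict = json.loads(bytes(z["__config__"]).decode())
        for key in ("widths", "stem_kernel", "stem_stride", "block2_stride"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = MResLSTM(ModelConfig(**cfg_dict))
        model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
    return model
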