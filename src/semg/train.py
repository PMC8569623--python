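"""Training, evaluation and the four-configuration ablation study.

The user-facing surface follows the estimator/results convention:
:class:`GestureClassifier` is built from an :class:`ArrayDataset` (or
directly from recordings) and a :class:`ModelConfig`; calling :meth:`fit`
trains the network and returns a :class:`GestureFitResults` carrying the
fitted network, the per-epoch history, validation metrics and a
``summary()`` table. The module-level :func:`train`/:func:`evaluate`
functions are the thin procedural equivalents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DimensionError
from .nn.autograd import softmax_cross_entropy
from .nn.layers import Adam
from .nn.network import ModelConfig, MResLSTM
from .pipeline import ArrayDataset, PipelineConfig, build_arrays
from .synthetic import NoiseConfig, Recording, generate_dataset

__all__ = ["TrainConfig", "Metrics", "split_dataset", "train", "evaluate",
           "GestureClassifier", "GestureFitResults",
           "AblationSuite", "run_ablation", "ABLATION_EXPERIMENTS"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults mirror the study protocol)."""
    batch_size: int = 128
    epochs: int = 200
    optimizer: str = "adam"
    lr: float = 1e-3
    seed: int = 0
    device: str = "cpu"
    cosine_decay: bool = True
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class Metrics:
    """Evaluation results. Recall of a class absent from the test set is NaN."""
    accuracy: float
    per_class_recall: np.ndarray
    confusion: np.ndarray
    loss_history: list | None = None

    def __repr__(self):
        return f"Metrics(accuracy={self.accuracy:.4f})"


def split_dataset(recordings: list[Recording], n_train_per_class: int,
                  n_test_per_class: int, seed: int):
    """Disjoint class-balanced random split of a recording collection."""
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {}
    for i, rec in enumerate(recordings):
        by_class.setdefault(rec.label, []).append(i)
    train_idx, test_idx = [], []
    need = n_train_per_class + n_test_per_class
    for label in sorted(by_class):
        idx = by_class[label]
        if len(idx) < need:
            raise ConfigurationError(
                f"class {label}: have {len(idx)} recordings, need {need}")
        perm = rng.permutation(len(idx))
        chosen = [idx[p] for p in perm[:need]]
        train_idx.extend(chosen[:n_train_per_class])
        test_idx.extend(chosen[n_train_per_class:])
    return ([recordings[i] for i in train_idx],
            [recordings[i] for i in test_idx])


def _iterate_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train(model_cfg: ModelConfig, train_cfg: TrainConfig,
          train_data: ArrayDataset, val_data: ArrayDataset | None = None):
    """Minimize cross-entropy; return (best-validation model, history).

    All randomness (init, shuffling, dropout) derives from train_cfg.seed.
    Aborts with a diagnostic on NaN loss. When no validation data is given
    the final-epoch weights are returned.
    """
    model = MResLSTM(model_cfg, seed=train_cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 0xBA7]))
    steps_per_epoch = math.ceil(len(train_data) / train_cfg.batch_size)
    opt = Adam(model.parameters(), lr=train_cfg.lr,
               cosine_decay_steps=(steps_per_epoch * train_cfg.epochs
                                   if train_cfg.cosine_decay else None))
    acc_in = train_data.acc if model_cfg.use_acc else None
    history = []
    best = (-1.0, None)
    for epoch in range(train_cfg.epochs):
        model.train()
        losses = []
        for batch in _iterate_batches(len(train_data), train_cfg.batch_size, rng):
            logits = model.forward(train_data.X[batch],
                                   None if acc_in is None else acc_in[batch])
            loss, _ = softmax_cross_entropy(logits, train_data.y[batch])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss {loss.data} at epoch "
                    f"{epoch + 1} (lr={opt.lr:.3g}); lower the learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        rec = {"epoch": epoch + 1, "train_loss": float(np.mean(losses))}
        if val_data is not None:
            vm = evaluate(model, val_data)
            rec["val_accuracy"] = vm.accuracy
            if vm.accuracy > best[0]:
                best = (vm.accuracy, model.state_dict())
        history.append(rec)
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    return model, history


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                             n_classes: int) -> Metrics:
    """Confusion-matrix bookkeeping shared by every evaluation path."""
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (np.asarray(y_true), np.asarray(y_pred)), 1)
    row = confusion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        recall = np.where(row > 0, np.diag(confusion) / np.maximum(row, 1), np.nan)
    return Metrics(accuracy=float(np.trace(confusion) / confusion.sum()),
                   per_class_recall=recall, confusion=confusion)


def evaluate(model: MResLSTM, test_data: ArrayDataset) -> Metrics:
    """Accuracy, per-class recall and confusion matrix in inference mode."""
    if len(test_data) == 0:
        raise ConfigurationError("empty test set")
    acc_in = test_data.acc if model.cfg.use_acc else None
    pred = model.predict(test_data.X, acc_in)
    return metrics_from_predictions(test_data.y, pred, model.cfg.n_classes)


# ---------------------------------------------------------------------------
# estimator / results surface

class GestureClassifier:
    """Gesture-classification model bound to data.

    Parameters
    ----------
    train_data : ArrayDataset
        Windowed network inputs with integer labels.
    model_config : ModelConfig, optional
        Architecture; inferred input shape overrides in_height/in_width.
    """

    def __init__(self, train_data: ArrayDataset,
                 model_config: ModelConfig | None = None):
        self.data = train_data
        H, W = train_data.X.shape[2], train_data.X.shape[3]
        if model_config is None:
            model_config = ModelConfig(in_height=H, in_width=W,
                                       input_mode=train_data.mode)
        elif (model_config.in_height, model_config.in_width) != (H, W):
            raise DimensionError(
                f"data windows are {H}x{W} but config declares "
                f"{model_config.in_height}x{model_config.in_width}")
        self.model_config = model_config

    @classmethod
    def from_recordings(cls, recordings: list[Recording],
                        pipeline: PipelineConfig = PipelineConfig(),
                        model_config: ModelConfig | None = None):
        data, norm = build_arrays(recordings, pipeline,
                                  fit_normalizer=(pipeline.mode == "feature"))
        obj = cls(data, model_config)
        obj.pipeline = pipeline
        obj.normalizer = norm
        return obj

    def fit(self, train_config: TrainConfig = TrainConfig()) -> "GestureFitResults":
        """Train with a stratified validation split; return the results object."""
        n = len(self.data)
        rng = np.random.default_rng(np.random.SeedSequence([train_config.seed, 0x5C]))
        val_mask = np.zeros(n, dtype=bool)
        if train_config.val_fraction > 0:
            for label in np.unique(self.data.y):
                idx = np.flatnonzero(self.data.y == label)
                k = max(1, int(round(train_config.val_fraction * len(idx))))
                val_mask[rng.choice(idx, size=k, replace=False)] = True
        tr = ArrayDataset(self.data.X[~val_mask], self.data.acc[~val_mask],
                          self.data.y[~val_mask], self.data.mode)
        va = (ArrayDataset(self.data.X[val_mask], self.data.acc[val_mask],
                           self.data.y[val_mask], self.data.mode)
              if val_mask.any() else None)
        model, history = train(self.model_config, train_config, tr, va)
        return GestureFitResults(self, model, history, train_config)


class GestureFitResults:
    """Fitted network + training history + evaluation helpers."""

    def __init__(self, estimator: GestureClassifier, model: MResLSTM,
                 history: list[dict], train_config: TrainConfig):
        self.estimator = estimator
        self.model = model
        self.history = history
        self.train_config = train_config

    @property
    def val_accuracy(self) -> float | None:
        accs = [h.get("val_accuracy") for h in self.history
                if "val_accuracy" in h]
        return max(accs) if accs else None

    def evaluate(self, test_data: ArrayDataset) -> Metrics:
        return evaluate(self.model, test_data)

    def predict(self, emg, acc=None):
        return self.model.predict(emg, acc)

    def summary(self):
        """Key facts of the fit as a two-column DataFrame."""
        import pandas as pd
        cfg = self.estimator.model_config
        rows = [
            ("input mode", cfg.input_mode),
            ("streams", cfg.streams),
            ("use ACC branch", cfg.use_acc),
            ("trainable parameters", self.model.n_parameters()),
            ("epochs", self.train_config.epochs),
            ("batch size", self.train_config.batch_size),
            ("final train loss", round(self.history[-1]["train_loss"], 4)),
            ("best val accuracy", self.val_accuracy),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def plot_history(self, ax=None):
        """Loss / validation-accuracy curves (matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        epochs = [h["epoch"] for h in self.history]
        ax.plot(epochs, [h["train_loss"] for h in self.history], label="train loss")
        if "val_accuracy" in self.history[0]:
            ax2 = ax.twinx()
            ax2.plot(epochs, [h["val_accuracy"] for h in self.history],
                     color="C1", label="val accuracy")
            ax2.set_ylabel("validation accuracy")
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy")
        return ax


# ---------------------------------------------------------------------------
# ablation study

# experiment 1 is the plain single-network baseline: one stream over the
# whole image and no recurrent temporal stage (window features averaged)
ABLATION_EXPERIMENTS = (
    ("exp1_single_raw", dict(streams=1, mode="raw", use_acc=False,
                             use_lstm=False)),
    ("exp2_multi_raw", dict(streams=4, mode="raw", use_acc=False,
                            use_lstm=True)),
    ("exp3_multi_raw_acc", dict(streams=4, mode="raw", use_acc=True,
                                use_lstm=True)),
    ("exp4_multi_feature_acc", dict(streams=4, mode="feature", use_acc=True,
                                    use_lstm=True)),
)


@dataclass(frozen=True)
class AblationSuite:
    """Study conditions for the four-configuration comparison.

    The four experiments — single-stream raw, multi-stream raw, multi-stream
    raw + ACC, multi-stream feature + ACC — are trained on identical data
    per seed and their test accuracies tabulated.
    """
    n_classes: int = 6
    n_train_per_class: int = 20
    n_test_per_class: int = 15
    fs: float = 1000.0
    duration_s: float = 1.6
    snr_db: float = 12.0
    seeds: tuple[int, ...] = (0, 1, 2)
    epochs: int = 15
    batch_size: int = 16
    lr: float = 3e-3
    n_windows: int = 5
    widths: tuple[int, int] = (8, 16)
    lstm_hidden: int = 16
    fc_hidden: int = 32


def _ablation_model_config(suite: AblationSuite, mode: str, streams: int,
                           use_acc: bool, use_lstm: bool,
                           in_height: int, in_width: int) -> ModelConfig:
    raw = mode == "raw"
    return ModelConfig(
        n_classes=suite.n_classes, streams=streams, input_mode=mode,
        in_height=in_height, in_width=in_width, widths=suite.widths,
        groups=2, se_ratio=4, lstm_hidden=suite.lstm_hidden,
        fc_hidden=suite.fc_hidden, use_acc=use_acc, use_lstm=use_lstm,
        stem_kernel=(3, 9) if raw else (3, 3),
        stem_stride=(1, 4) if raw else (1, 1),
        block2_stride=(2, 2) if raw else (1, 1))


def run_ablation(suite: AblationSuite = AblationSuite(), verbose: bool = False):
    """Train the four configurations on identical data; return a DataFrame.

    Columns: experiment, seed, accuracy; plus the per-experiment mean over
    seeds is available via ``df.groupby("experiment").accuracy.mean()``.
    """
    import pandas as pd
    rows = []
    for seed in suite.seeds:
        cfg_noise = NoiseConfig(snr_db=suite.snr_db, seed=seed)
        train_recs, test_recs = generate_dataset(
            suite.n_train_per_class, suite.n_test_per_class, suite.n_classes,
            suite.fs, cfg_noise, duration_s=suite.duration_s)
        arrays: dict[str, tuple] = {}
        for mode in ("raw", "feature"):
            pipe = PipelineConfig(mode=mode, n_windows=suite.n_windows)
            tr, norm = build_arrays(train_recs, pipe,
                                    fit_normalizer=(mode == "feature"))
            te, _ = build_arrays(test_recs, pipe, normalizer=norm)
            arrays[mode] = (tr, te)
        for name, recipe in ABLATION_EXPERIMENTS:
            tr, te = arrays[recipe["mode"]]
            mc = _ablation_model_config(suite, recipe["mode"], recipe["streams"],
                                        recipe["use_acc"], recipe["use_lstm"],
                                        tr.X.shape[2], tr.X.shape[3])
            tc = TrainConfig(batch_size=suite.batch_size, epochs=suite.epochs,
                             lr=suite.lr, seed=seed, val_fraction=0.0)
            model, history = train(mc, tc, tr, None)
            acc = evaluate(model, te).accuracy
            rows.append({"experiment": name, "seed": seed, "accuracy": acc,
                         "final_train_loss": history[-1]["train_loss"]})
            if verbose:
                print(f"seed {seed} {name}: accuracy {acc:.3f}")
    return pd.DataFrame(rows)
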