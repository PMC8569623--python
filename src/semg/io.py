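"""HDF5 and CSV persistence for recordings and feature stores."""

from __future__ import annotations

import os

import h5py
import numpy as np

from .synthetic import Recording

__all__ = ["save_recording", "load_recording", "save_dataset", "load_dataset",
           "export_csv", "save_feature_store", "load_feature_store"]


def save_recording(path, rec: Recording) -> None:
    """Write one recording: datasets /semg, /acc (+ /envelope), attrs fs/label/subject."""
    with h5py.File(path, "w") as f:
        f.create_dataset("semg", data=rec.semg)
        f.create_dataset("acc", data=rec.acc)
        if rec.envelope is not None:
            f.create_dataset("envelope", data=rec.envelope)
        f.attrs["fs"] = rec.fs
        f.attrs["label"] = rec.label
        f.attrs["subject"] = rec.subject


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        label = f.attrs["label"]
        if isinstance(label, (np.integer, int)):
            label = int(label)
        else:
            label = str(label)
        return Recording(
            semg=f["semg"][...], acc=f["acc"][...],
            fs=float(f.attrs["fs"]), label=label,
            subject=str(f.attrs["subject"]),
            envelope=f["envelope"][...] if "envelope" in f else None)


def save_dataset(directory, recordings: list[Recording], prefix: str = "rec") -> list[str]:
    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, rec in enumerate(recordings):
        p = os.path.join(directory, f"{prefix}{i:05d}.h5")
        save_recording(p, rec)
        paths.append(p)
    return paths


def load_dataset(directory, prefix: str = "rec") -> list[Recording]:
    names = sorted(n for n in os.listdir(directory)
                   if n.startswith(prefix) and n.endswith(".h5"))
    return [load_recording(os.path.join(directory, n)) for n in names]


def export_csv(path, rec: Recording) -> None:
    """Per-channel CSV: time column + one column per EMG channel + ACC axes."""
    t = np.arange(rec.n_samples) / rec.fs
    cols = [t] + [rec.semg[c] for c in range(rec.n_channels)] + list(rec.acc)
    header = (["time_s"] + [f"emg_ch{c}" for c in range(rec.n_channels)]
              + ["acc_x", "acc_y", "acc_z"])
    np.savetxt(path, np.column_stack(cols), delimiter=",",
               header=",".join(header), comments="")


def save_feature_store(path, X_raw=None, X_feat=None, y=None) -> None:
    """Windowed arrays: /X_raw [N,T,C,L], /X_feat [N,T,4,C], /y [N]."""
    with h5py.File(path, "w") as f:
        if X_raw is not None:
            f.create_dataset("X_raw", data=X_raw)
        if X_feat is not None:
            f.create_dataset("X_feat", data=X_feat)
        if y is not None:
            f.create_dataset("y", data=np.asarray(y))


def load_feature_store(path) -> dict:
    with h5py.File(path, "r") as f:
        return {k: f[k][...] for k in f.keys()}
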