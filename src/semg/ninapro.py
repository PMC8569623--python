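"""Adapter for Ninapro DB1-style MAT recordings (52 hand movements).

Maps the benchmark's MAT-file layout onto :class:`~semg.synthetic.Recording`
objects so the conditioning/imaging/training pipeline can consume them
unchanged (with ``ModelConfig(n_classes=52)``). The benchmark itself is an
external download and is not exercised by this package's tests.

Expected MAT variables (per the DB1 distribution):

* ``emg``      — [T x 10] sEMG, 100 Hz
* ``acc``      — [T x 3] accelerometer (when present)
* ``stimulus`` (or ``restimulus``) — [T x 1] movement label per sample,
  0 = rest
* ``subject``  — scalar subject id
"""

from __future__ import annotations

import numpy as np

from .synthetic import Recording

__all__ = ["load_ninapro_mat"]

NINAPRO_DB1_FS = 100.0


def load_ninapro_mat(path, fs: float = NINAPRO_DB1_FS,
                     use_restimulus: bool = True) -> list[Recording]:
    """Split one subject MAT file into per-repetition recordings.

    Each maximal run of a nonzero stimulus label becomes one Recording
    whose label is ``stimulus - 1`` (0-based movement id). Requires
    scipy.io; raises FileNotFoundError / KeyError on malformed files.
    """
    from scipy.io import loadmat

    mat = loadmat(path)
    emg = np.asarray(mat["emg"], dtype=np.float64).T          # [C, T]
    key = "restimulus" if use_restimulus and "restimulus" in mat else "stimulus"
    stim = np.asarray(mat[key]).ravel().astype(int)
    acc = (np.asarray(mat["acc"], dtype=np.float64).T[:3]
           if "acc" in mat else np.zeros((3, emg.shape[1])))
    subject = str(int(np.asarray(mat.get("subject", 0)).ravel()[0]))

    recordings: list[Recording] = []
    boundaries = np.flatnonzero(np.diff(stim) != 0) + 1
    for a, b in zip(np.r_[0, boundaries], np.r_[boundaries, stim.size]):
        label = stim[a]
        if label == 0:
            continue
        recordings.append(Recording(
            semg=emg[:, a:b].copy(), acc=acc[:, a:b].copy(), fs=fs,
            label=int(label) - 1, subject=f"S{subject}"))
    return recordings
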