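"""HDF5 / CSV / JSON input-output for tensors, factors and sessions."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .tensor import Tensor3

__all__ = ["save_tensor", "load_tensor", "save_session", "load_session",
           "save_factors_csv"]


def save_tensor(path, t: Tensor3, name: str = "tensor") -> None:
    """Write a three-way tensor to HDF5 with its mode names as attributes."""
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=t.data)
        ds.attrs["mode_names"] = [str(m) for m in t.mode_names]


def load_tensor(path, name: str = "tensor") -> Tensor3:
    with h5py.File(path, "r") as f:
        ds = f[name]
        data = ds[()]
        modes = tuple(
            m.decode() if isinstance(m, bytes) else str(m)
            for m in ds.attrs.get("mode_names", ("mode1", "mode2", "mode3"))
        )
    return Tensor3(data, modes)


def save_session(directory, meg: np.ndarray, eeg: np.ndarray, metadata: dict) -> None:
    """Write a session: per-modality signal arrays (HDF5) + metadata JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with h5py.File(directory / "signals.h5", "w") as f:
        f.create_dataset("MEG", data=np.asarray(meg))
        f.create_dataset("EEG", data=np.asarray(eeg))
    (directory / "metadata.json").write_text(json.dumps(metadata, indent=2))


def load_session(directory):
    directory = Path(directory)
    with h5py.File(directory / "signals.h5", "r") as f:
        meg = f["MEG"][()]
        eeg = f["EEG"][()]
    metadata = json.loads((directory / "metadata.json").read_text())
    return meg, eeg, metadata


def load_signals_edf(path):
    """Read multichannel signals from an EDF file (returns data, labels, sfreq)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(), list(raw.ch_names), float(raw.info["sfreq"])


def save_factors_csv(directory, model, prefix: str) -> None:
    """One CSV per factor matrix; columns are components."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for n, f in enumerate(model.factors, start=1):
        cols = {f"component_{r + 1}": f[:, r] for r in range(f.shape[1])}
        import pandas as pd

        pd.DataFrame(cols).to_csv(directory / f"{prefix}_factor{n}.csv", index=False)
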