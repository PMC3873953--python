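"""On-disk layouts for epoch sets.

Two interchangeable layouts, both bit-exact on round trip:

* directory layout — one ``.npy`` array per epoch plus a ``manifest.csv``
  with the labels, sampling rate and event index;
* single HDF5 container — one ``epochs`` dataset plus label arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import EpochSet

__all__ = [
    "write_epochs_dir",
    "read_epochs_dir",
    "write_epochs_hdf5",
    "read_epochs_hdf5",
]

_MANIFEST = "manifest.csv"
_META = "meta.json"


def write_epochs_dir(epochs: EpochSet, path) -> Path:
    """One .npy file per epoch plus a CSV manifest; returns the directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = epochs.labels.copy()
    files = []
    for e in range(epochs.n_epochs):
        fname = f"epoch_{e:06d}.npy"
        np.save(path / fname, epochs.data[e])
        files.append(fname)
    manifest["file"] = files
    manifest.to_csv(path / _MANIFEST, index=False)
    (path / _META).write_text(
        json.dumps(
            {"sampling_rate_hz": epochs.sampling_rate_hz, "event_index": epochs.event_index}
        )
    )
    return path


def read_epochs_dir(path) -> EpochSet:
    path = Path(path)
    meta = json.loads((path / _META).read_text())
    manifest = pd.read_csv(path / _MANIFEST)
    data = np.stack([np.load(path / f) for f in manifest["file"]]) if len(manifest) else (
        np.empty((0, 0, 0))
    )
    labels = manifest.drop(columns="file")
    return EpochSet(data, meta["sampling_rate_hz"], labels, meta["event_index"])


def write_epochs_hdf5(epochs: EpochSet, path) -> Path:
    """Single-container layout: /epochs dataset + one dataset per label column."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data)
        f.attrs["sampling_rate_hz"] = epochs.sampling_rate_hz
        f.attrs["event_index"] = epochs.event_index
        grp = f.create_group("labels")
        for col in epochs.labels.columns:
            values = epochs.labels[col].to_numpy()
            if values.dtype == object:
                values = values.astype("S")
            grp.create_dataset(col, data=values)
        grp.attrs["columns"] = json.dumps(list(epochs.labels.columns))
    return path


def read_epochs_hdf5(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["epochs"][...]
        fs = float(f.attrs["sampling_rate_hz"])
        event_index = int(f.attrs["event_index"])
        columns = json.loads(f["labels"].attrs["columns"])
        labels = {}
        for col in columns:
            values = f["labels"][col][...]
            if values.dtype.kind == "S":
                values = values.astype(str)
            labels[col] = values
    return EpochSet(data, fs, pd.DataFrame(labels), event_index)
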