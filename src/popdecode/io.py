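"""Disk I/O: TSV trial/response tables, HDF5 epoch containers, MNE export."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .taskgen import SensorEpochs


def save_epochs_h5(epochs: SensorEpochs, path) -> None:
    """Write a SensorEpochs container (data + time axis + trial table)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("times_ms", data=epochs.times_ms)
        if epochs.sensor_locations is not None:
            f.create_dataset("sensor_locations", data=epochs.sensor_locations)
        f.attrs["sensor_labels"] = json.dumps(epochs.sensor_labels)
        f.attrs["trials"] = epochs.trials.to_json(orient="split")


def load_epochs_h5(path) -> SensorEpochs:
    with h5py.File(path, "r") as f:
        trials = pd.read_json(
            __import__("io").StringIO(f.attrs["trials"]), orient="split")
        loc = f["sensor_locations"][()] if "sensor_locations" in f else None
        return SensorEpochs(
            data=f["data"][()],
            times_ms=f["times_ms"][()],
            trials=trials,
            sensor_labels=json.loads(f.attrs["sensor_labels"]),
            sensor_locations=loc,
        )


def to_mne_epochs(epochs: SensorEpochs):
    """Export to an mne.EpochsArray (misc channels) for interoperability."""
    import mne

    info = mne.create_info(epochs.sensor_labels, sfreq=1000.0 / epochs.dt_ms,
                           ch_types="misc")
    return mne.EpochsArray(epochs.data, info,
                           tmin=epochs.times_ms[0] / 1000.0, verbose="error")
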