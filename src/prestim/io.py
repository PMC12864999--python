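"""Reading and writing recordings, TFR volumes and result tables.

The native on-disk format is a small documented HDF5 layout::

    /data            float32 (n_channels, n_samples), microvolts
    /events/sample   int64
    /events/code     variable-length strings
    attrs: sfreq (Hz), ch_names (list of str)

EDF and BrainVision recordings are read through MNE when available.
"""

from __future__ import annotations

from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .containers import Recording
from .timefreq import TFRVolume


def write_recording_h5(recording: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data.astype(np.float64),
                         compression="gzip", compression_opts=1)
        f.attrs["sfreq"] = recording.sfreq
        f.attrs["ch_names"] = [str(c) for c in recording.ch_names]
        grp = f.create_group("events")
        grp.create_dataset(
            "sample", data=recording.events["sample"].to_numpy(dtype=np.int64)
        )
        grp.create_dataset(
            "code",
            data=np.array(recording.events["code"], dtype=object),
            dtype=h5py.string_dtype(),
        )


def read_recording_h5(path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        sfreq = float(f.attrs["sfreq"])
        ch_names = [str(c) for c in f.attrs["ch_names"]]
        if "events" not in f:
            raise ValueError(f"{path}: missing events group")
        events = pd.DataFrame({
            "sample": f["events/sample"][()].astype(int),
            "code": [c.decode() if isinstance(c, bytes) else str(c)
                     for c in f["events/code"][()]],
        })
    return Recording(data=data, sfreq=sfreq, ch_names=ch_names, events=events)


def _recording_from_mne_raw(raw, stim_annotations: bool = True) -> Recording:
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = []
    for ann in raw.annotations:
        events.append({
            "sample": int(round(ann["onset"] * raw.info["sfreq"])),
            "code": str(ann["description"]),
        })
    return Recording(
        data=data, sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        events=pd.DataFrame(events, columns=["sample", "code"]),
    )


def read_eeg(path, fmt: Optional[str] = None) -> Recording:
    """Read a continuous recording (internal HDF5, EDF, or BrainVision)."""
    p = str(path)
    if fmt is None:
        if p.endswith((".h5", ".hdf5")):
            fmt = "hdf5"
        elif p.endswith(".edf"):
            fmt = "edf"
        elif p.endswith(".vhdr"):
            fmt = "brainvision"
        else:
            raise ValueError(f"cannot infer format of {p}")
    if fmt == "hdf5":
        return read_recording_h5(p)
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF/BrainVision requires mne") from exc
    if fmt == "edf":
        raw = mne.io.read_raw_edf(p, preload=True, verbose="error")
    elif fmt == "brainvision":
        raw = mne.io.read_raw_brainvision(p, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return _recording_from_mne_raw(raw)


def write_tfr_h5(tfr: TFRVolume, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=tfr.power, compression="gzip",
                         compression_opts=1)
        f.create_dataset("freqs", data=tfr.freqs)
        f.create_dataset("times", data=tfr.times)
        f.attrs["ch_names"] = [str(c) for c in tfr.ch_names]
        f.attrs["baseline_mode"] = tfr.baseline_mode
        f.attrs["baseline_window"] = list(tfr.baseline_window)


def read_tfr_h5(path) -> TFRVolume:
    with h5py.File(path, "r") as f:
        return TFRVolume(
            power=f["power"][()], freqs=f["freqs"][()], times=f["times"][()],
            ch_names=[str(c) for c in f.attrs["ch_names"]],
            baseline_mode=str(f.attrs["baseline_mode"]),
            baseline_window=tuple(f.attrs["baseline_window"]),
        )
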