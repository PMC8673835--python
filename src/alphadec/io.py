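"""Readers and writers for the artefact formats.

Synthetic recordings round-trip through HDF5; rating traces through CSV
(columns: second, rating); ground truth through JSON.  Real EEG files
(EDF, BrainVision) are read via mne.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import GroundTruth, RatingTrace, Recording

__all__ = [
    "save_recording_hdf5",
    "load_recording_hdf5",
    "save_ratings_csv",
    "load_ratings_csv",
    "save_ground_truth_json",
    "load_ground_truth_json",
    "read_eeg_file",
    "save_ssd_hdf5",
]


def save_recording_hdf5(rec: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = rec.fs
        f.attrs["cropped"] = rec.cropped
        f.create_dataset("segment_marks", data=np.asarray(rec.segment_marks, dtype=int))
        f.create_dataset(
            "channel_labels", data=np.array(rec.channel_labels, dtype="S")
        )


def load_recording_hdf5(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            channel_labels=tuple(s.decode() for s in f["channel_labels"][()]),
            segment_marks=tuple(int(m) for m in f["segment_marks"][()]),
            cropped=bool(f.attrs["cropped"]),
        )


def save_ratings_csv(trace: RatingTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"second": np.arange(trace.values.size), "rating": trace.values}
    ).to_csv(path, index=False)


def load_ratings_csv(path: str | Path, quantized: bool = True) -> RatingTrace:
    df = pd.read_csv(path)
    return RatingTrace(values=df["rating"].to_numpy(float), quantized=quantized)


def save_ground_truth_json(gt: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(gt.to_json())


def load_ground_truth_json(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        mixing_matrix=np.asarray(d["mixing_matrix"], dtype=float),
        arousal_source_index=int(d["arousal_source_index"]),
        source_envelope=np.asarray(d["source_envelope"], dtype=float),
        coupling_kappa=float(d["coupling_kappa"]),
    )


def read_eeg_file(path: str | Path) -> Recording:
    """Read an EDF or BrainVision recording into a :class:`Recording`.

    Data are converted to µV.  Segment marks are not inferred; set them
    from the experiment's event structure before cropping.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG container: {path.suffix}")
    return Recording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )


def save_ssd_hdf5(res, path: str | Path) -> None:
    """Persist SSD filters, patterns and eigenvalues."""
    with h5py.File(path, "w") as f:
        f.create_dataset("filters_W", data=res.filters_W)
        f.create_dataset("patterns_A", data=res.patterns_A)
        f.create_dataset("eigenvalues", data=res.eigenvalues)
        f.create_dataset("selected", data=np.asarray(res.selected, dtype=int))
        f.attrs["fs"] = res.fs
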