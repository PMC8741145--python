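"""Serialization: HDF5 containers for arrays, TSV for tables, EDF reading.

Continuous recordings and epoch sets travel as HDF5 (datasets ``data``,
``time_s``; attributes ``fs_hz``, channel labels, baseline interval) with
sidecar TSV tables for events, annotations and trial metadata.  EDF/BDF
files from real acquisition systems can be read through :mod:`mne` when it
is installed; recordings are not written back to EDF.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .simulate import ContinuousRecording
from .spectral import ITCSeries, TFRSet


def save_recording(rec: ContinuousRecording, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip", track_times=False)
        f.attrs["fs_hz"] = rec.fs_hz
        f.attrs["channel_labels"] = list(rec.channel_labels)
        f.attrs["history"] = json.dumps(rec.history)
    rec.events.to_csv(path.with_suffix(".events.tsv"), sep="\t", index=False, na_rep="NA")
    rec.annotations.to_csv(
        path.with_suffix(".annotations.tsv"), sep="\t", index=False
    )


def load_recording(path) -> ContinuousRecording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs_hz"])
        labels = tuple(str(x) for x in f.attrs["channel_labels"])
        history = json.loads(f.attrs.get("history", "[]"))
    events = pd.read_csv(path.with_suffix(".events.tsv"), sep="\t", na_values=["NA"])
    ann_path = path.with_suffix(".annotations.tsv")
    annotations = (
        pd.read_csv(ann_path, sep="\t")
        if ann_path.exists()
        else pd.DataFrame(columns=["kind", "start_s", "end_s"])
    )
    return ContinuousRecording(
        data=data, fs_hz=fs, channel_labels=labels,
        events=events, annotations=annotations, history=list(history),
    )


def save_epochs(epochs: EpochSet, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", track_times=False)
        f.create_dataset("time_s", data=epochs.time_s, track_times=False)
        f.attrs["fs_hz"] = epochs.fs_hz
        f.attrs["channel_labels"] = list(epochs.channel_labels)
        f.attrs["lock"] = epochs.lock
        if epochs.baseline_interval_s is not None:
            f.attrs["baseline_interval_s"] = list(epochs.baseline_interval_s)
    epochs.meta.to_csv(path.with_suffix(".meta.tsv"), sep="\t", index=False, na_rep="NA")


def load_epochs(path) -> EpochSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        time_s = f["time_s"][()]
        fs = float(f.attrs["fs_hz"])
        labels = tuple(str(x) for x in f.attrs["channel_labels"])
        lock = str(f.attrs.get("lock", "target"))
        baseline = f.attrs.get("baseline_interval_s")
    meta = pd.read_csv(path.with_suffix(".meta.tsv"), sep="\t", na_values=["NA"])
    return EpochSet(
        data=data, time_s=time_s, fs_hz=fs, channel_labels=labels, meta=meta,
        baseline_interval_s=None if baseline is None else tuple(baseline),
        lock=lock,
    )


def save_tfr(tfr: TFRSet, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=tfr.power, track_times=False)
        f.create_dataset("freqs_hz", data=tfr.freqs_hz, track_times=False)
        f.create_dataset("times_s", data=tfr.times_s, track_times=False)
        if tfr.baseline is not None:
            f.create_dataset("baseline", data=tfr.baseline, track_times=False)
            f.create_dataset("power_db", data=tfr.power_db, track_times=False)
        f.attrs["kind"] = tfr.kind
        f.attrs["db_convention"] = "10*log10(P / mean prestimulus P per frequency)"
        if tfr.roi is not None:
            f.attrs["roi"] = tfr.roi.name
        if tfr.baseline_interval_s is not None:
            f.attrs["baseline_interval_s"] = list(tfr.baseline_interval_s)


def tfr_to_tsv(tfr: TFRSet, path) -> None:
    """Long-format TSV: freq_hz, time_s, power, power_db (if baselined)."""
    ff, tt = np.meshgrid(tfr.freqs_hz, tfr.times_s, indexing="ij")
    table = pd.DataFrame(
        {"freq_hz": ff.ravel(), "time_s": tt.ravel(), "power": tfr.power.ravel()}
    )
    if tfr.baseline is not None:
        table["power_db"] = tfr.power_db.ravel()
    table.to_csv(path, sep="\t", index=False)


def itc_to_tsv(series: ITCSeries, path) -> None:
    table = pd.DataFrame({"time_s": series.times_s, "itc": series.itc})
    if series.sig_mask is not None:
        table["significant"] = series.sig_mask
    table.to_csv(path, sep="\t", index=False)


def read_raw_edf(path, **kwargs) -> ContinuousRecording:
    """Read an EDF/BDF recording through mne into a ContinuousRecording.

    Events and annotations must be supplied separately (TSV tables); mne
    annotations of kind 'blink'/'bad_segment' are carried over when present.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF/BDF requires the 'mne' package") from exc
    path = str(path)
    reader = mne.io.read_raw_bdf if path.lower().endswith(".bdf") else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error", **kwargs)
    data_uv = raw.get_data() * 1e6
    ann_rows = [
        (desc if desc in ("blink", "bad_segment") else "bad_segment", on, on + dur)
        for on, dur, desc in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
    ]
    return ContinuousRecording(
        data=data_uv,
        fs_hz=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        events=pd.DataFrame(columns=["onset_s", "stim", "half", "responded", "rt_s"]),
        annotations=pd.DataFrame(ann_rows, columns=["kind", "start_s", "end_s"]),
    )
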