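"""Readers and writers for the package's delimited table formats.

A recording session on disk is a directory with:

* ``intensity.csv`` — one column per channel (header = channel IDs)
* ``channels.csv``  — sidecar with ``channel_id, sd_distance_mm``
* ``rpeaks.txt``    — one R-peak time (seconds) per line
* ``session.yaml``  — sampling rate and free-form metadata

Derived products (pulsation waveforms, fiducial and index tables, audit
logs) are plain CSV so every intermediate is inspectable. A minimal SNIRF
(HDF5) export/import is provided for interoperability with NiRS tooling.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

from .signals import ArterialPulsationSignal, RawChannel, RPeakEvents


# --- session tables ---------------------------------------------------------

def write_session(directory, channels: list[RawChannel],
                  events: RPeakEvents) -> pathlib.Path:
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({c.channel_id: c.samples for c in channels}).to_csv(
        d / "intensity.csv", index=False)
    pd.DataFrame({
        "channel_id": [c.channel_id for c in channels],
        "sd_distance_mm": [c.sd_distance for c in channels],
    }).to_csv(d / "channels.csv", index=False)
    np.savetxt(d / "rpeaks.txt", events.times, fmt="%.6f")
    (d / "session.yaml").write_text(yaml.safe_dump(
        {"fs_hz": float(channels[0].fs)}))
    return d


def read_session(directory) -> tuple[list[RawChannel], RPeakEvents]:
    d = pathlib.Path(directory)
    meta = yaml.safe_load((d / "session.yaml").read_text())
    fs = float(meta["fs_hz"])
    table = pd.read_csv(d / "intensity.csv")
    sidecar = pd.read_csv(d / "channels.csv").set_index("channel_id")
    channels = [
        RawChannel(samples=table[cid].to_numpy(), fs=fs, channel_id=str(cid),
                   sd_distance=float(sidecar.loc[cid, "sd_distance_mm"]))
        for cid in table.columns
    ]
    events = RPeakEvents(np.loadtxt(d / "rpeaks.txt", ndmin=1))
    return channels, events


# --- derived products -------------------------------------------------------

def write_pulsation_signals(path, signals: list[ArterialPulsationSignal]):
    """Per-channel s waveforms, long format with acquisition metadata."""
    frames = []
    for s in signals:
        frames.append(pd.DataFrame({
            "channel_id": s.channel_id,
            "time_s": np.round(s.times, 6),
            "amplitude": s.samples,
            "fs_hz": s.fs,
            "epoch_length_s": s.epoch_length,
            "n_epochs_averaged": s.n_epochs_averaged,
            "median_rr_s": s.median_rr,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_pulsation_signals(path) -> list[ArterialPulsationSignal]:
    table = pd.read_csv(path)
    out = []
    for cid, grp in table.groupby("channel_id", sort=False):
        out.append(ArterialPulsationSignal(
            samples=grp["amplitude"].to_numpy(),
            fs=float(grp["fs_hz"].iloc[0]),
            epoch_length=float(grp["epoch_length_s"].iloc[0]),
            n_epochs_averaged=int(grp["n_epochs_averaged"].iloc[0]),
            median_rr=float(grp["median_rr_s"].iloc[0]),
            channel_id=str(cid)))
    return out


def write_table(path, frame: pd.DataFrame, float_format: str = "%.6f"):
    frame.to_csv(path, index=False, float_format=float_format)


# --- SNIRF (optional HDF5 container) ----------------------------------------

def write_snirf(path, channels: list[RawChannel], events: RPeakEvents):
    """Minimal single-wavelength SNIRF export.

    Source/detector positions are laid out on the x-axis so that each
    channel's source-detector separation equals its ``sd_distance`` (mm);
    R-peak events are stored as a stimulus group.
    """
    import h5py

    n = len(channels[0].samples)
    fs = channels[0].fs
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset(
            "dataTimeSeries",
            data=np.column_stack([c.samples for c in channels]))
        data.create_dataset("time", data=np.arange(n) / fs)
        probe = nirs.create_group("probe")
        src = np.zeros((len(channels), 3))
        det = np.zeros((len(channels), 3))
        det[:, 0] = [c.sd_distance for c in channels]
        probe.create_dataset("sourcePos3D", data=src)
        probe.create_dataset("detectorPos3D", data=det)
        probe.create_dataset("wavelengths", data=[830.0])
        for i, c in enumerate(channels, start=1):
            ml = data.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex", data=i)
            ml.create_dataset("detectorIndex", data=i)
            ml.create_dataset("wavelengthIndex", data=1)
            ml.create_dataset("dataType", data=1)
            ml.create_dataset("name", data=c.channel_id)
        stim = nirs.create_group("stim1")
        stim.create_dataset("name", data="r_peak")
        stim.create_dataset(
            "data", data=np.column_stack([
                events.times, np.zeros_like(events.times),
                np.ones_like(events.times)]))


def read_snirf(path) -> tuple[list[RawChannel], RPeakEvents]:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        series = data["dataTimeSeries"][()]
        time = data["time"][()]
        fs = 1.0 / float(np.median(np.diff(time)))
        src = f["nirs/probe/sourcePos3D"][()]
        det = f["nirs/probe/detectorPos3D"][()]
        channels = []
        for i in range(series.shape[1]):
            ml = data[f"measurementList{i + 1}"]
            s_idx = int(ml["sourceIndex"][()]) - 1
            d_idx = int(ml["detectorIndex"][()]) - 1
            dist = float(np.linalg.norm(src[s_idx] - det[d_idx]))
            name = ml["name"][()]
            if isinstance(name, bytes):
                name = name.decode()
            channels.append(RawChannel(
                samples=series[:, i], fs=fs, channel_id=str(name),
                sd_distance=dist))
        events = RPeakEvents(f["nirs/stim1/data"][()][:, 0])
    return channels, events
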