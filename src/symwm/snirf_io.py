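"""SNIRF (HDF5) reading and writing for simulated recordings.

The container follows the SNIRF layout: intensity in
``/nirs/data1/dataTimeSeries`` with one measurementList entry per
channel x wavelength, probe wavelengths, stimulus groups per condition,
and auxiliary traces under ``/nirs/aux*``.  Montage metadata (channel
ids, separations, ROI labels, short flags) is carried in a JSON side
dataset so recordings round-trip losslessly within the package.
"""

from __future__ import annotations

import json
import warnings

import h5py
import numpy as np
import pandas as pd

from .montage import Channel, Montage
from .schedule import CONDITIONS
from .synth_fnirs import RawRecording


def write_snirf(recording: RawRecording, path) -> None:
    """Write a recording (intensity, events, aux, montage) as SNIRF."""
    n, nch, nwl = recording.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        # flatten (channel, wavelength) -> measurement columns
        flat = recording.intensity.reshape(n, nch * nwl)
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=np.arange(n) / recording.fs)
        m = 1
        for i, ch in enumerate(recording.montage.channels):
            for w in range(nwl):
                g = data.create_group(f"measurementList{m}")
                g.create_dataset("sourceIndex", data=ch.source_id)
                g.create_dataset("detectorIndex", data=ch.detector_id)
                g.create_dataset("wavelengthIndex", data=w + 1)
                g.create_dataset("dataType", data=1)
                g.create_dataset("dataTypeIndex", data=1)
                m += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(recording.montage.wavelengths))
        for k, cond in enumerate(CONDITIONS, start=1):
            ev = recording.events[recording.events["condition"] == cond]
            g = nirs.create_group(f"stim{k}")
            g.create_dataset("name", data=np.bytes_(cond))
            arr = np.column_stack([ev["onset_s"], ev["duration_s"],
                                   np.ones(len(ev))]) if len(ev) else np.empty((0, 3))
            g.create_dataset("data", data=arr)
        for k, (name, series) in enumerate(sorted(recording.aux.items()), start=1):
            g = nirs.create_group(f"aux{k}")
            g.create_dataset("name", data=np.bytes_(name))
            g.create_dataset("time", data=np.arange(len(series)) / recording.fs)
            g.create_dataset("dataTimeSeries", data=np.asarray(series))
        meta = [{"channel_id": c.channel_id, "source_id": c.source_id,
                 "detector_id": c.detector_id, "separation_mm": c.separation_mm,
                 "roi": c.roi, "is_short": c.is_short}
                for c in recording.montage.channels]
        nirs.create_dataset("symwmMontage", data=np.bytes_(json.dumps(
            {"fs": recording.fs, "channels": meta})))


def read_snirf(path) -> RawRecording:
    """Read a SNIRF file written by :func:`write_snirf`."""
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise ValueError(f"malformed SNIRF container: missing /nirs in {path}")
        nirs = f["nirs"]
        if "data1" not in nirs:
            raise ValueError("malformed SNIRF container: missing /nirs/data1")
        flat = nirs["data1/dataTimeSeries"][()]
        meta = json.loads(bytes(nirs["symwmMontage"][()]).decode())
        channels = [Channel(channel_id=c["channel_id"], source_id=c["source_id"],
                            detector_id=c["detector_id"],
                            separation_mm=c["separation_mm"], roi=c["roi"],
                            is_short=c["is_short"]) for c in meta["channels"]]
        wavelengths = tuple(nirs["probe/wavelengths"][()])
        montage = Montage(channels=channels, wavelengths=wavelengths)
        n = flat.shape[0]
        intensity = flat.reshape(n, len(channels), len(wavelengths))
        rows = []
        for key in sorted(k for k in nirs if k.startswith("stim")):
            name = bytes(nirs[key]["name"][()]).decode()
            for onset, dur, _ in np.atleast_2d(nirs[key]["data"][()]):
                rows.append({"onset_s": onset, "duration_s": dur, "condition": name})
        events = pd.DataFrame(rows, columns=["onset_s", "duration_s", "condition"])
        events = events.sort_values("onset_s", kind="stable").reset_index(drop=True)
        aux = {}
        aux_keys = [k for k in nirs if k.startswith("aux")]
        if not aux_keys:
            warnings.warn("SNIRF file contains no aux group; recording loads without aux")
        for key in aux_keys:
            name = bytes(nirs[key]["name"][()]).decode()
            aux[name] = nirs[key]["dataTimeSeries"][()]
        return RawRecording(intensity=intensity, fs=float(meta["fs"]),
                            events=events, montage=montage, aux=aux)
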