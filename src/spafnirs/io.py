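"""Readers and writers for the documented interchange formats.

A session is serialized as a TSV trio — ``intensities.tsv`` (time + one
column per channel x wavelength), ``aux.tsv`` (time + physiology columns,
one file per sensor rate would be lossy, so each sensor keeps its own time
column), ``events.tsv`` (onset, duration, condition; BIDS-events dialect) —
plus ``optodes.tsv`` (label, x, y, z, kind) for digitized scans. A minimal
SNIRF (HDF5) export/import is provided for interoperability.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import AUX_FS_HZ, SIGNALS, AuxSeries, DigitizedScan, EventSchedule, SessionRecording

__all__ = [
    "write_session_tsv",
    "read_session_tsv",
    "write_scan_tsv",
    "read_scan_tsv",
    "write_snirf",
    "read_snirf",
]


def write_session_tsv(recording: SessionRecording, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t = np.arange(recording.n_times) / recording.fs_hz
    cols = {"time": t}
    for i, name in enumerate(recording.channel_names):
        for w, wl in enumerate(recording.wavelengths):
            cols[f"{name}@{wl:g}nm"] = recording.intensities[i, w]
    pd.DataFrame(cols).to_csv(out / "intensities.tsv", sep="\t", index=False)

    aux_frames = []
    for name, series in recording.aux.items():
        ta = np.arange(len(series.values)) / series.fs_hz
        aux_frames.append(pd.DataFrame({"time": ta, "signal": name, "value": series.values}))
    pd.concat(aux_frames).to_csv(out / "aux.tsv", sep="\t", index=False)

    pd.DataFrame(
        [{"onset": o, "duration": d, "trial_type": c} for o, d, c in recording.events]
    ).to_csv(out / "events.tsv", sep="\t", index=False)


def read_session_tsv(indir, subject_id: str = "S01", session_id: int = 1) -> SessionRecording:
    indir = Path(indir)
    inten = pd.read_csv(indir / "intensities.tsv", sep="\t")
    t = inten.pop("time").to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    names: list[str] = []
    for col in inten.columns:
        ch = col.split("@")[0]
        if ch not in names:
            names.append(ch)
    wls = sorted({float(col.split("@")[1].replace("nm", "")) for col in inten.columns})
    arr = np.empty((len(names), len(wls), len(inten)))
    for i, ch in enumerate(names):
        for w, wl in enumerate(wls):
            arr[i, w] = inten[f"{ch}@{wl:g}nm"].to_numpy()

    aux: dict[str, AuxSeries] = {}
    aux_tab = pd.read_csv(indir / "aux.tsv", sep="\t")
    for name, grp in aux_tab.groupby("signal"):
        ta = grp["time"].to_numpy()
        fs_aux = 1.0 / np.median(np.diff(ta)) if len(ta) > 1 else 1.0
        aux[name] = AuxSeries(grp["value"].to_numpy(), float(round(fs_aux, 3)))
    missing = [s for s in SIGNALS if s not in aux]
    if missing:
        warnings.warn(f"aux roster incomplete; missing {missing}", RuntimeWarning)

    ev = pd.read_csv(indir / "events.tsv", sep="\t")
    events = EventSchedule(
        [(float(r.onset), float(r.duration), str(r.trial_type)) for r in ev.itertuples()]
    )
    return SessionRecording(arr, names, aux, events, subject_id, session_id,
                            fs_hz=float(round(fs, 4)), wavelengths=tuple(wls))


def write_scan_tsv(scan: DigitizedScan, path, montage=None) -> None:
    rows = []
    for name, xyz in scan.fiducials.items():
        rows.append(dict(label=name, x=xyz[0], y=xyz[1], z=xyz[2], kind="fiducial"))
    srcs = set(montage.source_names) if montage is not None else set()
    for name, xyz in scan.optode_coords.items():
        kind = "source" if name in srcs else "detector" if montage is not None else "optode"
        rows.append(dict(label=name, x=xyz[0], y=xyz[1], z=xyz[2], kind=kind))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scan_tsv(path, subject_id: str = "S01", session_id: int = 1) -> DigitizedScan:
    tab = pd.read_csv(path, sep="\t")
    fids, opts = {}, {}
    for r in tab.itertuples():
        xyz = np.array([r.x, r.y, r.z], dtype=float)
        if r.kind == "fiducial":
            fids[r.label] = xyz
        else:
            opts[r.label] = xyz
    return DigitizedScan(fids, opts, subject_id, session_id)


# ---------------------------------------------------------------------------
# SNIRF (HDF5) interchange, v1.0 layout


def write_snirf(recording: SessionRecording, path) -> None:
    import h5py

    n_ch = len(recording.channel_names)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=recording.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")

        data = nirs.create_group("data1")
        t = np.arange(recording.n_times) / recording.fs_hz
        data.create_dataset("time", data=t)
        # columns: channel-major, wavelength-minor
        dt = np.empty((recording.n_times, n_ch * 2))
        col = 0
        srcs, dets = [], []
        for name in recording.channel_names:
            s, d = name.split("-", 1)
            if s not in srcs:
                srcs.append(s)
            if d not in dets:
                dets.append(d)
        for i, name in enumerate(recording.channel_names):
            s, d = name.split("-", 1)
            for w in range(2):
                dt[:, col] = recording.intensities[i, w]
                ml = data.create_group(f"measurementList{col + 1}")
                ml.create_dataset("sourceIndex", data=srcs.index(s) + 1)
                ml.create_dataset("detectorIndex", data=dets.index(d) + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                col += 1
        data.create_dataset("dataTimeSeries", data=dt)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(recording.wavelengths))
        probe.create_dataset("sourceLabels", data=np.array(srcs, dtype="S"))
        probe.create_dataset("detectorLabels", data=np.array(dets, dtype="S"))

        for k, (name, series) in enumerate(recording.aux.items(), start=1):
            aux = nirs.create_group(f"aux{k}")
            aux.create_dataset("name", data=name)
            aux.create_dataset("dataTimeSeries", data=series.values)
            aux.create_dataset("time", data=np.arange(len(series.values)) / series.fs_hz)

        for j, cond in enumerate(sorted({c for _, _, c in recording.events}), start=1):
            stim = nirs.create_group(f"stim{j}")
            stim.create_dataset("name", data=cond)
            rows = [[o, d, 1.0] for o, d, c in recording.events if c == cond]
            stim.create_dataset("data", data=np.array(rows))


def read_snirf(path, subject_id: str | None = None, session_id: int = 1) -> SessionRecording:
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        t = data["time"][()]
        fs = 1.0 / np.median(np.diff(t))
        dt = data["dataTimeSeries"][()]
        srcs = [s.decode() for s in nirs["probe"]["sourceLabels"][()]]
        dets = [d.decode() for d in nirs["probe"]["detectorLabels"][()]]
        wls = tuple(nirs["probe"]["wavelengths"][()])
        ml_keys = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k.replace("measurementList", "")),
        )
        chan_order: list[str] = []
        colmap: dict[tuple[str, int], int] = {}
        for col, k in enumerate(ml_keys):
            ml = data[k]
            name = f"{srcs[int(ml['sourceIndex'][()]) - 1]}-{dets[int(ml['detectorIndex'][()]) - 1]}"
            w = int(ml["wavelengthIndex"][()]) - 1
            if name not in chan_order:
                chan_order.append(name)
            colmap[(name, w)] = col
        arr = np.empty((len(chan_order), len(wls), len(t)))
        for i, name in enumerate(chan_order):
            for w in range(len(wls)):
                arr[i, w] = dt[:, colmap[(name, w)]]

        aux: dict[str, AuxSeries] = {}
        for k in sorted(key for key in nirs.keys() if key.startswith("aux")):
            g = nirs[k]
            name = g["name"][()]
            name = name.decode() if isinstance(name, bytes) else str(name)
            ta = g["time"][()]
            fs_aux = 1.0 / np.median(np.diff(ta)) if len(ta) > 1 else 1.0
            aux[name] = AuxSeries(g["dataTimeSeries"][()], float(round(fs_aux, 3)))
        if not aux:
            warnings.warn(
                "SNIRF file carries no aux physiology; denoising restricted to "
                "'none'/'ss'", RuntimeWarning)

        events = []
        for k in sorted(key for key in nirs.keys() if key.startswith("stim")):
            g = nirs[k]
            cond = g["name"][()]
            cond = cond.decode() if isinstance(cond, bytes) else str(cond)
            for row in g["data"][()]:
                events.append((float(row[0]), float(row[1]), cond))
        events.sort(key=lambda e: e[0])
        meta_sid = f["nirs"]["metaDataTags"]["SubjectID"][()]
        meta_sid = meta_sid.decode() if isinstance(meta_sid, bytes) else str(meta_sid)

    return SessionRecording(arr, chan_order, aux, EventSchedule(events),
                            subject_id or meta_sid, session_id,
                            fs_hz=float(round(fs, 4)), wavelengths=wls)
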