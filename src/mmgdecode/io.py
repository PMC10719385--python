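"""HDF5 / TSV input-output.

Recordings and envelopes live in HDF5 containers: dataset ``/data``
(channels x samples, float32) with attributes ``fs`` and ``session_id`` and a
``/channels`` table (name, modality, axis, side); envelopes use ``/envelope``
instead of ``/data``. Event tables are sidecar TSV files with the header
``onset_s  duration_s  label``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import Channel, EnvelopeSeries, EventTable, Recording
from .windows import Moments, WindowDataset

_CHANNEL_FIELDS = ("name", "modality", "axis", "side")


def _write_channels(f: h5py.File, channels: list[Channel]) -> None:
    dt = h5py.string_dtype()
    arr = np.array(
        [tuple(getattr(c, fld) for fld in _CHANNEL_FIELDS) for c in channels],
        dtype=[(fld, dt) for fld in _CHANNEL_FIELDS],
    )
    f.create_dataset("channels", data=arr)


def _read_channels(f: h5py.File) -> list[Channel]:
    rows = f["channels"][()]
    return [
        Channel(*(v.decode() if isinstance(v, bytes) else str(v) for v in row))
        for row in rows
    ]


def save_recording(path: str | Path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.data.astype(np.float32))
        d.attrs["fs"] = rec.fs
        d.attrs["session_id"] = rec.session_id
        _write_channels(f, rec.channels)


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        d = f["data"]
        return Recording(
            data=d[()].astype(float),
            fs=float(d.attrs["fs"]),
            channels=_read_channels(f),
            session_id=str(d.attrs.get("session_id", "")),
        )


def save_envelope(path: str | Path, env: EnvelopeSeries) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("envelope", data=env.data.astype(np.float32))
        d.attrs["fs"] = env.fs
        d.attrs["session_id"] = env.session_id
        _write_channels(f, env.channels)


def load_envelope(path: str | Path) -> EnvelopeSeries:
    with h5py.File(path, "r") as f:
        d = f["envelope"]
        return EnvelopeSeries(
            data=np.clip(d[()].astype(float), 0.0, None),
            fs=float(d.attrs["fs"]),
            channels=_read_channels(f),
            session_id=str(d.attrs.get("session_id", "")),
        )


def save_events(path: str | Path, events: EventTable) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False)


def load_events(path: str | Path, label_set=("DII", "DV")) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    return EventTable.from_frame(df, label_set=label_set)


def save_dataset(path: str | Path, ds: WindowDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ds.X.astype(np.float32))
        y = f.create_dataset("y", data=ds.y.astype(np.int64))
        y.attrs["labels"] = list(ds.labels)
        y.attrs["split"] = ds.split
        if ds.moments is not None:
            f.create_dataset("moments/mean", data=ds.moments.mean)
            f.create_dataset("moments/sd", data=ds.moments.sd)
        f.create_dataset("positions", data=np.array(
            [(p.session, p.start, p.trial) for p in ds.positions], dtype=np.int64
        ))


def load_dataset(path: str | Path) -> WindowDataset:
    from .windows import WindowPosition

    with h5py.File(path, "r") as f:
        moments = None
        if "moments" in f:
            moments = Moments(mean=f["moments/mean"][()], sd=f["moments/sd"][()])
        positions = [
            WindowPosition(session=int(s), start=int(st), trial=int(t))
            for s, st, t in f["positions"][()]
        ]
        return WindowDataset(
            X=f["X"][()].astype(float),
            y=f["y"][()].astype(int),
            labels=tuple(str(x) for x in f["y"].attrs["labels"]),
            split=str(f["y"].attrs["split"]),
            positions=positions,
            moments=moments,
        )
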