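"""Session readers and writers.

HDF5 is the canonical container (raw traces need binary storage); a CSV
directory is the human-readable dialect carrying the same spike and
protocol tables (without raw traces).

HDF5 layout::

    /spikes/<cell_id>/times      float64 seconds; attrs channel_id, unit_index
    /protocols/<protocol_id>     dataset "onsets"; attrs kind, amplitude_uA,
                                 phase_duration_ms, on/off durations, n_repeats
    /raw/<channel_id>            optional int16 samples + attr scale_uV
    root attrs                   session_id, sampling_rate_hz, group_label

CSV directory: spikes.csv (cell_id, channel_id, unit_index, time_s),
protocols.csv, onsets.csv (protocol_id, onset_s), channel_map.csv,
session.csv (key, value).
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    RecordingSession,
    SessionValidationError,
    SpikeTrain,
    StimulusProtocol,
)

log = logging.getLogger("rgcestim")

_FLOAT_FMT = "%.17g"  # deterministic CSV floats, exact float64 round-trip


def write_session(session: RecordingSession, path, format: str = "hdf5") -> Path:
    """Write a session; returns the path written.

    Output is deterministic for identical inputs: keys are written sorted
    and CSV floats use a fixed format.
    """
    path = Path(path)
    if format == "hdf5":
        _write_hdf5(session, path)
    elif format == "csv_dir":
        _write_csv_dir(session, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_session(path, format: str | None = None) -> RecordingSession:
    """Read a session from an HDF5 file or a CSV directory.

    The format is inferred from the path when not given (directory ->
    csv_dir).  Validation errors name the offending table or cell.
    """
    path = Path(path)
    if format is None:
        format = "csv_dir" if path.is_dir() else "hdf5"
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "csv_dir":
        return _read_csv_dir(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

def _protocol_attrs(p: StimulusProtocol) -> dict:
    attrs: dict = {"kind": p.kind}
    if p.kind == "electrical":
        attrs["amplitude_uA"] = float(p.amplitude_uA)
        attrs["phase_duration_ms"] = float(p.phase_duration_ms)
        attrs["polarity"] = p.polarity
    else:
        attrs["on_duration_s"] = float(p.on_duration_s)
        attrs["off_duration_s"] = float(p.off_duration_s)
        attrs["n_repeats"] = int(p.n_repeats)
    return attrs


def _write_hdf5(session: RecordingSession, path: Path) -> None:
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["session_id"] = session.session_id
        f.attrs["sampling_rate_hz"] = float(session.sampling_rate)
        f.attrs["group_label"] = session.group_label
        f.create_dataset(
            "channel_map", data=np.asarray(sorted(session.channel_map), dtype=np.int64)
        )
        spikes = f.create_group("spikes")
        for train in sorted(session.spike_trains, key=lambda t: t.cell_id):
            g = spikes.create_group(train.cell_id)
            g.create_dataset("times", data=train.times, dtype=np.float64)
            g.attrs["channel_id"] = int(train.channel_id)
            g.attrs["unit_index"] = int(train.unit_index)
        protos = f.create_group("protocols")
        for p in sorted(session.protocols, key=lambda p: p.protocol_id):
            g = protos.create_group(p.protocol_id)
            g.create_dataset("onsets", data=p.onsets, dtype=np.float64)
            for k, v in _protocol_attrs(p).items():
                g.attrs[k] = v
        if session.raw_traces:
            raw = f.create_group("raw")
            for cid in sorted(session.raw_traces):
                trace = np.asarray(session.raw_traces[cid], dtype=float)
                scale = max(np.abs(trace).max() / 32000.0, 1e-12)
                ds = raw.create_dataset(
                    str(cid), data=np.round(trace / scale).astype(np.int16)
                )
                ds.attrs["scale_uV"] = scale


def _read_hdf5(path: Path) -> RecordingSession:
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for block in ("spikes", "protocols"):
            if block not in f:
                raise SessionValidationError(f"missing mandatory table '{block}'")
        known = {"spikes", "protocols", "raw", "channel_map", "truth"}
        for key in f:
            if key not in known:
                log.warning("ignoring unknown block %r", key)
        channel_map = [tuple(int(v) for v in row) for row in f["channel_map"][()]] if (
            "channel_map" in f
        ) else None
        trains = []
        for cell_id in sorted(f["spikes"]):
            g = f["spikes"][cell_id]
            times = g["times"][()]
            if times.size and np.any(times < 0):
                raise SessionValidationError(
                    f"negative spike time in cell {cell_id}"
                )
            try:
                trains.append(
                    SpikeTrain(
                        cell_id=cell_id,
                        channel_id=int(g.attrs["channel_id"]),
                        unit_index=int(g.attrs["unit_index"]),
                        times=times,
                    )
                )
            except SessionValidationError as err:
                raise SessionValidationError(f"cell {cell_id}: {err}") from err
        protocols = []
        for pid in sorted(f["protocols"]):
            g = f["protocols"][pid]
            kind = g.attrs["kind"]
            protocols.append(
                StimulusProtocol(
                    protocol_id=pid,
                    kind=kind,
                    onsets=g["onsets"][()],
                    amplitude_uA=float(g.attrs["amplitude_uA"])
                    if "amplitude_uA" in g.attrs
                    else None,
                    phase_duration_ms=float(g.attrs["phase_duration_ms"])
                    if "phase_duration_ms" in g.attrs
                    else None,
                    on_duration_s=float(g.attrs["on_duration_s"])
                    if "on_duration_s" in g.attrs
                    else None,
                    off_duration_s=float(g.attrs["off_duration_s"])
                    if "off_duration_s" in g.attrs
                    else None,
                    n_repeats=int(g.attrs["n_repeats"])
                    if "n_repeats" in g.attrs
                    else None,
                )
            )
        raw = None
        if "raw" in f:
            raw = {}
            for cid in f["raw"]:
                ds = f["raw"][cid]
                raw[int(cid)] = ds[()].astype(float) * float(ds.attrs["scale_uV"])
        kwargs = {}
        if channel_map is not None:
            kwargs["channel_map"] = channel_map
        return RecordingSession(
            session_id=str(f.attrs["session_id"]),
            sampling_rate=float(f.attrs["sampling_rate_hz"]),
            spike_trains=trains,
            protocols=protocols,
            group_label=str(f.attrs["group_label"]),
            raw_traces=raw,
            **kwargs,
        )


def write_truth(path, truth: pd.DataFrame) -> None:
    """Append a ground-truth table to an existing session HDF5 (/truth)."""
    with h5py.File(path, "a") as f:
        if "truth" in f:
            del f["truth"]
        g = f.create_group("truth")
        for col in sorted(truth.columns):
            vals = truth[col].to_numpy()
            if vals.dtype == object or str(vals.dtype).startswith("str"):
                vals = np.asarray(
                    ["" if v is None else str(v) for v in vals], dtype="S64"
                )
            elif vals.dtype == bool:
                vals = vals.astype(np.int8)
            else:
                vals = np.asarray(
                    [np.nan if v is None else v for v in vals], dtype=float
                )
            g.create_dataset(col, data=vals)


def read_truth(path) -> pd.DataFrame:
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            raise SessionValidationError("missing mandatory table 'truth'")
        data = {}
        for col in f["truth"]:
            vals = f["truth"][col][()]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() for v in vals])
            data[col] = vals
    truth = pd.DataFrame(data)
    if "cell_id" in truth.columns:
        truth = truth.set_index("cell_id", drop=False)
    return truth


# ---------------------------------------------------------------------------
# CSV directory
# ---------------------------------------------------------------------------

def _write_csv_dir(session: RecordingSession, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    spike_rows = []
    for train in sorted(session.spike_trains, key=lambda t: t.cell_id):
        for t in train.times:
            spike_rows.append(
                (train.cell_id, train.channel_id, train.unit_index, t)
            )
    pd.DataFrame(
        spike_rows, columns=["cell_id", "channel_id", "unit_index", "time_s"]
    ).to_csv(path / "spikes.csv", index=False, float_format=_FLOAT_FMT)
    proto_rows, onset_rows = [], []
    for p in sorted(session.protocols, key=lambda p: p.protocol_id):
        proto_rows.append(
            {
                "protocol_id": p.protocol_id,
                "kind": p.kind,
                "amplitude_uA": p.amplitude_uA,
                "phase_duration_ms": p.phase_duration_ms,
                "on_duration_s": p.on_duration_s,
                "off_duration_s": p.off_duration_s,
                "n_repeats": p.n_repeats,
            }
        )
        for t in p.onsets:
            onset_rows.append((p.protocol_id, t))
    pd.DataFrame(proto_rows).to_csv(
        path / "protocols.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(onset_rows, columns=["protocol_id", "onset_s"]).to_csv(
        path / "onsets.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(
        sorted(session.channel_map), columns=["channel_id", "grid_row", "grid_col"]
    ).to_csv(path / "channel_map.csv", index=False)
    pd.DataFrame(
        [
            ("session_id", session.session_id),
            ("sampling_rate_hz", _FLOAT_FMT % session.sampling_rate),
            ("group_label", session.group_label),
        ],
        columns=["key", "value"],
    ).to_csv(path / "session.csv", index=False)


def _read_csv_dir(path: Path) -> RecordingSession:
    if not path.is_dir():
        raise FileNotFoundError(path)
    for name in ("spikes.csv", "protocols.csv", "onsets.csv", "session.csv"):
        if not (path / name).exists():
            raise SessionValidationError(f"missing mandatory table '{name}'")
    meta = dict(
        pd.read_csv(path / "session.csv", dtype=str).itertuples(index=False, name=None)
    )
    spikes = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    trains = []
    if len(spikes):
        for cell_id, sub in spikes.groupby("cell_id", sort=True):
            times = sub["time_s"].to_numpy(dtype=float)
            if np.any(times < 0):
                raise SessionValidationError(f"negative spike time in cell {cell_id}")
            trains.append(
                SpikeTrain(
                    cell_id=str(cell_id),
                    channel_id=int(sub["channel_id"].iloc[0]),
                    unit_index=int(sub["unit_index"].iloc[0]),
                    times=times,
                )
            )
    protos_df = pd.read_csv(path / "protocols.csv")
    onsets_df = pd.read_csv(path / "onsets.csv", float_precision="round_trip")
    protocols = []
    for row in protos_df.itertuples(index=False):
        onsets = onsets_df.loc[
            onsets_df["protocol_id"] == row.protocol_id, "onset_s"
        ].to_numpy(dtype=float)
        protocols.append(
            StimulusProtocol(
                protocol_id=str(row.protocol_id),
                kind=str(row.kind),
                onsets=onsets,
                amplitude_uA=None if pd.isna(row.amplitude_uA) else float(row.amplitude_uA),
                phase_duration_ms=None
                if pd.isna(row.phase_duration_ms)
                else float(row.phase_duration_ms),
                on_duration_s=None if pd.isna(row.on_duration_s) else float(row.on_duration_s),
                off_duration_s=None
                if pd.isna(row.off_duration_s)
                else float(row.off_duration_s),
                n_repeats=None if pd.isna(row.n_repeats) else int(row.n_repeats),
            )
        )
    kwargs = {}
    cm_path = path / "channel_map.csv"
    if cm_path.exists():
        cm = pd.read_csv(cm_path)
        kwargs["channel_map"] = [
            (int(r.channel_id), int(r.grid_row), int(r.grid_col))
            for r in cm.itertuples(index=False)
        ]
    return RecordingSession(
        session_id=meta["session_id"],
        sampling_rate=float(meta["sampling_rate_hz"]),
        spike_trains=trains,
        protocols=protocols,
        group_label=meta["group_label"],
        **kwargs,
    )
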