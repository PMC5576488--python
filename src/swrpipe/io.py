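"""On-disk session format.

A session directory holds::

    position.csv      time_s,x_cm,y_cm
    units.csv         unit_id,region,spike_width_ms
    spikes.csv        unit_id,time_s
    lfp.h5            dataset "samples" (time x channel, float64)
    lfp.json          {"sample_rate_hz": ..., "channel_ids": [...], "t0_s": ...}
    wells.csv         well_id,x_cm,y_cm,radius_cm
    well_events.csv   time_s,well_id,kind
    metadata.json     free-form key/value

``lfp.csv`` (``time_s,<ch>,...``) is accepted as a plain-text alternative
to ``lfp.h5`` when reading.  Output is deterministic: identical sessions
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import (
    LfpBundle,
    PositionTrace,
    Session,
    SpikeTrain,
    ValidationError,
    WellEvent,
    WellGeometry,
)

__all__ = ["read_session", "write_session", "SessionFormatError"]


class SessionFormatError(ValueError):
    """A session file is missing or malformed."""


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise SessionFormatError(f"missing file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise SessionFormatError(f"{path}: {exc}") from exc
    if list(df.columns) != columns:
        raise SessionFormatError(
            f"{path}: expected header {','.join(columns)}, got {','.join(df.columns)}"
        )
    return df


def read_session(directory: str | Path) -> Session:
    """Read and fully validate a session directory.

    Raises :class:`SessionFormatError` naming the offending file (and unit,
    for spike-order violations) on any malformed input.
    """
    d = Path(directory)
    pos_df = _read_csv(d / "position.csv", ["time_s", "x_cm", "y_cm"])
    try:
        position = PositionTrace(
            pos_df["time_s"].to_numpy(), pos_df["x_cm"].to_numpy(),
            pos_df["y_cm"].to_numpy(),
        )
    except ValidationError as exc:
        raise SessionFormatError(f"{d / 'position.csv'}: {exc}") from exc

    units_df = _read_csv(d / "units.csv", ["unit_id", "region", "spike_width_ms"])
    spikes_df = _read_csv(d / "spikes.csv", ["unit_id", "time_s"])
    spikes_by_unit = {
        uid: grp["time_s"].to_numpy() for uid, grp in spikes_df.groupby("unit_id", sort=False)
    }
    units: list[SpikeTrain] = []
    for row in units_df.itertuples(index=False):
        uid = str(row.unit_id)
        times = spikes_by_unit.get(uid)
        if times is None or times.size == 0:
            raise SessionFormatError(
                f"{d / 'spikes.csv'}: unit {uid!r} has zero spikes"
            )
        try:
            units.append(SpikeTrain(uid, str(row.region), times, float(row.spike_width_ms)))
        except ValidationError as exc:
            raise SessionFormatError(f"{d / 'spikes.csv'}: {exc}") from exc
    extra = set(spikes_by_unit) - {u.unit_id for u in units}
    if extra:
        raise SessionFormatError(
            f"{d / 'spikes.csv'}: spikes for units absent from units.csv: {sorted(extra)}"
        )

    lfp = _read_lfp(d)

    wells_df = _read_csv(d / "wells.csv", ["well_id", "x_cm", "y_cm", "radius_cm"])
    try:
        wells = [
            WellGeometry(str(r.well_id), float(r.x_cm), float(r.y_cm), float(r.radius_cm))
            for r in wells_df.itertuples(index=False)
        ]
    except ValidationError as exc:
        raise SessionFormatError(f"{d / 'wells.csv'}: {exc}") from exc

    events_path = d / "well_events.csv"
    well_events: list[WellEvent] = []
    if events_path.exists():
        ev_df = _read_csv(events_path, ["time_s", "well_id", "kind"])
        try:
            well_events = [
                WellEvent(float(r.time_s), str(r.well_id), str(r.kind))
                for r in ev_df.itertuples(index=False)
            ]
        except ValidationError as exc:
            raise SessionFormatError(f"{events_path}: {exc}") from exc

    metadata = {}
    meta_path = d / "metadata.json"
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())

    try:
        return Session(position, units, lfp, wells, well_events, metadata)
    except ValidationError as exc:
        raise SessionFormatError(f"{d}: {exc}") from exc


def _read_lfp(d: Path) -> LfpBundle:
    sidecar = d / "lfp.json"
    if not sidecar.exists():
        raise SessionFormatError(f"missing file: {sidecar}")
    meta = json.loads(sidecar.read_text())
    h5_path = d / "lfp.h5"
    csv_path = d / "lfp.csv"
    if h5_path.exists():
        with h5py.File(h5_path, "r") as f:
            samples = f["samples"][...]
    elif csv_path.exists():
        df = pd.read_csv(csv_path, float_precision="round_trip")
        if df.columns[0] != "time_s":
            raise SessionFormatError(f"{csv_path}: first column must be time_s")
        samples = df.iloc[:, 1:].to_numpy(dtype=float)
    else:
        raise SessionFormatError(f"missing file: {h5_path} (or lfp.csv)")
    try:
        return LfpBundle(
            sample_rate_hz=float(meta["sample_rate_hz"]),
            channel_ids=[str(c) for c in meta["channel_ids"]],
            samples=samples,
            t0_s=float(meta.get("t0_s", 0.0)),
        )
    except ValidationError as exc:
        raise SessionFormatError(f"{h5_path}: {exc}") from exc


def write_session(session: Session, directory: str | Path) -> None:
    """Write a session directory (see module docstring for the layout)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    pos = session.position
    pd.DataFrame(
        {"time_s": pos.time_s, "x_cm": pos.x_cm, "y_cm": pos.y_cm}
    ).to_csv(d / "position.csv", index=False)

    pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in session.units],
            "region": [u.region for u in session.units],
            "spike_width_ms": [u.spike_width_ms for u in session.units],
        }
    ).to_csv(d / "units.csv", index=False)

    uid_col: list[str] = []
    t_col: list[np.ndarray] = []
    for u in session.units:
        uid_col.extend([u.unit_id] * u.n_spikes)
        t_col.append(u.spike_times_s)
    pd.DataFrame(
        {"unit_id": uid_col,
         "time_s": np.concatenate(t_col) if t_col else np.array([])}
    ).to_csv(d / "spikes.csv", index=False)

    with h5py.File(d / "lfp.h5", "w", track_order=False) as f:
        f.create_dataset("samples", data=session.lfp.samples, track_times=False)
    (d / "lfp.json").write_text(
        json.dumps(
            {
                "sample_rate_hz": session.lfp.sample_rate_hz,
                "channel_ids": session.lfp.channel_ids,
                "t0_s": session.lfp.t0_s,
            },
            sort_keys=True,
        )
    )

    pd.DataFrame(
        {
            "well_id": [w.well_id for w in session.wells],
            "x_cm": [w.x_cm for w in session.wells],
            "y_cm": [w.y_cm for w in session.wells],
            "radius_cm": [w.radius_cm for w in session.wells],
        }
    ).to_csv(d / "wells.csv", index=False)

    pd.DataFrame(
        {
            "time_s": [e.time_s for e in session.well_events],
            "well_id": [e.well_id for e in session.well_events],
            "kind": [e.kind for e in session.well_events],
        }
    ).to_csv(d / "well_events.csv", index=False)

    (d / "metadata.json").write_text(json.dumps(session.metadata, sort_keys=True))
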