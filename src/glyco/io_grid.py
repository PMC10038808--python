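"""Parsing and gridding of free-living pump--sensor records.

Raw exports from insulin pumps and CGM sensors arrive as irregular
per-timestamp rows mixing sparse diary entries (carbohydrate, bolus,
activity) with quasi-periodic sensor readings (CGM every ~5 minutes).
This module canonicalizes units and time and resamples everything onto
a uniform 5-minute grid with explicit missing-markers, the container
every downstream stage operates on.

Canonical conventions
---------------------
* time is Unix seconds (UTC); the grid step is 300 s;
* glucose is stored in mg/dL (1 mmol/L = 18.0182 mg/dL);
* missing values are NaN, with a parallel per-channel provenance code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("glyco")

GRID_STEP = 300
MGDL_PER_MMOLL = 18.0182

#: channels carried on the uniform grid, in canonical order
CHANNELS = (
    "cgm",
    "smbg",
    "basal_rate",
    "bolus",
    "duration",
    "activity_duration",
    "distance_value",
    "energy_value",
    "carbohydrate",
)

#: glucose-valued channels subject to unit conversion
GLUCOSE_CHANNELS = ("cgm", "smbg")

# provenance codes
PROV_MISSING = 0
PROV_OBSERVED = 1
PROV_IMPUTED = 2
PROV_REJECTED = 3


@dataclass
class SubjectRecord:
    """One raw per-timestamp observation (a subset of channels present)."""

    time: float  # Unix seconds
    values: dict[str, float] = field(default_factory=dict)
    activity_name: str | None = None


@dataclass
class GriddedSeries:
    """Uniform 5-minute multichannel series with missing-markers.

    ``channels[name]`` is a float vector of length ``n``; missing samples
    are NaN.  ``provenance[name]`` carries an int8 code per sample
    (missing / observed / imputed / rejected).
    """

    t0: int
    channels: dict[str, np.ndarray]
    provenance: dict[str, np.ndarray]
    step: int = GRID_STEP

    @property
    def n(self) -> int:
        return len(next(iter(self.channels.values())))

    def times(self) -> np.ndarray:
        return self.t0 + self.step * np.arange(self.n)

    def mask(self, channel: str) -> np.ndarray:
        """True where the channel is missing."""
        return np.isnan(self.channels[channel])

    def copy(self) -> "GriddedSeries":
        return GriddedSeries(
            t0=self.t0,
            channels={k: v.copy() for k, v in self.channels.items()},
            provenance={k: v.copy() for k, v in self.provenance.items()},
            step=self.step,
        )

    def day_index(self) -> np.ndarray:
        """UTC day ordinal of every grid sample."""
        return self.times() // 86400

    def seconds_of_day(self) -> np.ndarray:
        return self.times() % 86400


def empty_series(t0: int, n: int, channels=CHANNELS) -> GriddedSeries:
    return GriddedSeries(
        t0=int(t0),
        channels={c: np.full(n, np.nan) for c in channels},
        provenance={c: np.zeros(n, dtype=np.int8) for c in channels},
    )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def convert_glucose_units(value):
    """mmol/L -> mg/dL (18.0182 mg/dL per mmol/L); NaN passes through."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("negative glucose value")
    out = arr * MGDL_PER_MMOLL
    return float(out) if np.isscalar(value) else out


def _parse_time(x) -> float:
    if isinstance(x, (int, float)) and not isinstance(x, bool):
        return float(x)
    ts = pd.Timestamp(str(x))
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.timestamp()


def parse_dataset(path, schema: dict, glucose_unit: str = "mgdl") -> list[SubjectRecord]:
    """Read a delimited-text or JSON-lines export into :class:`SubjectRecord` rows.

    ``schema`` maps source column names to canonical channel names (plus
    ``time`` and optionally ``activity_name``).  Unparseable numeric cells
    become missing (counted in the log); duplicate (time, channel) pairs
    are collapsed first-wins.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if "time" not in schema.values():
        raise ValueError("schema must map a source column to 'time'")
    if path.suffix in (".jsonl", ".json"):
        df = pd.read_json(path, lines=True)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        log.warning("parse_dataset: %s is empty", path)
        return []
    missing_cols = [c for c in schema if c not in df.columns]
    if missing_cols:
        raise ValueError(f"columns not found in {path.name}: {missing_cols}")

    df = df.rename(columns=schema)
    n_bad = 0
    records: list[SubjectRecord] = []
    seen: set[tuple[float, str]] = set()
    n_dup = 0
    for _, row in df.iterrows():
        t = _parse_time(row["time"])
        vals: dict[str, float] = {}
        name = None
        for ch in schema.values():
            if ch in ("time",):
                continue
            raw = row.get(ch)
            if ch == "activity_name":
                if isinstance(raw, str) and raw:
                    name = raw
                continue
            v = pd.to_numeric(pd.Series([raw]), errors="coerce").iloc[0]
            if pd.isna(v):
                if raw is not None and not pd.isna(raw) and str(raw) != "":
                    n_bad += 1
                continue
            v = float(v)
            if ch in GLUCOSE_CHANNELS and glucose_unit == "mmol":
                v = convert_glucose_units(v)
            if (t, ch) in seen:
                n_dup += 1
                continue
            seen.add((t, ch))
            vals[ch] = v
        records.append(SubjectRecord(time=t, values=vals, activity_name=name))
    if n_bad:
        log.warning("parse_dataset: %d unparseable numeric cells -> missing", n_bad)
    if n_dup:
        log.warning("parse_dataset: %d duplicate (time, channel) values dropped", n_dup)
    return records


def to_unix_sorted(records: list[SubjectRecord]) -> list[SubjectRecord]:
    """Stable sort ascending by Unix timestamp."""
    return sorted(records, key=lambda r: r.time)


# ---------------------------------------------------------------------------
# gridding
# ---------------------------------------------------------------------------

def to_uniform_grid(records: list[SubjectRecord]) -> GriddedSeries:
    """Resample sorted records onto the uniform 300-s grid.

    The grid is anchored at the first observation's timestamp rounded down
    to a multiple of 300 s from midnight UTC so that time-of-day features
    align across days; length is ``floor((t_last - t_first)/300) + 1``.
    Observations snap to the nearest grid point (ties toward earlier);
    per-channel conflicts keep the first value.  Basal rate is expanded as
    a piecewise-constant profile between setting changes.
    """
    if not records:
        raise ValueError("no records to grid")
    t_first = records[0].time
    t_last = records[-1].time
    if t_last < t_first:
        raise ValueError("records must be sorted ascending")
    t0 = int(t_first - (t_first % GRID_STEP))
    n = int((t_last - t_first) // GRID_STEP) + 1
    series = empty_series(t0, n)
    n_conflict = 0
    for rec in records:
        pos = (rec.time - t0) / GRID_STEP
        # nearest grid point; exact .5 ties snap toward the earlier point
        idx = int(np.floor(pos + 0.5))
        if pos - np.floor(pos) == 0.5:
            idx = int(np.floor(pos))
        idx = min(max(idx, 0), n - 1)
        for ch, v in rec.values.items():
            if ch not in series.channels:
                continue
            if not np.isnan(series.channels[ch][idx]):
                n_conflict += 1
                continue
            series.channels[ch][idx] = v
            series.provenance[ch][idx] = PROV_OBSERVED
    if n_conflict:
        log.warning("to_uniform_grid: %d snapped observations conflicted (first kept)", n_conflict)
    _expand_basal(series)
    return series


def _expand_basal(series: GriddedSeries) -> None:
    """Piecewise-constant basal: hold each setting until the next change."""
    b = series.channels["basal_rate"]
    prov = series.provenance["basal_rate"]
    obs = np.flatnonzero(~np.isnan(b))
    for i, start in enumerate(obs):
        stop = obs[i + 1] if i + 1 < len(obs) else len(b)
        fill = np.arange(start + 1, stop)
        b[fill] = b[start]
        prov[fill] = PROV_OBSERVED


# ---------------------------------------------------------------------------
# persistence (CSV + JSON sidecar; HDF5 for pipelines)
# ---------------------------------------------------------------------------

def write_gridded(series: GriddedSeries, path) -> None:
    """Write a GriddedSeries to CSV with a JSON metadata sidecar.

    Floats are written with round-trippable precision so that
    read_gridded(write_gridded(s)) is bit-exact.
    """
    path = Path(path)
    cols: dict[str, np.ndarray] = {}
    for ch in series.channels:
        cols[ch] = series.channels[ch]
        cols[ch + "__prov"] = series.provenance[ch]
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {"t0": int(series.t0), "step": int(series.step),
            "channels": list(series.channels)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_gridded(path) -> GriddedSeries:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    channels = {c: df[c].to_numpy(dtype=float) for c in meta["channels"]}
    prov = {c: df[c + "__prov"].to_numpy(dtype=np.int8) for c in meta["channels"]}
    return GriddedSeries(t0=meta["t0"], channels=channels, provenance=prov,
                         step=meta["step"])


def write_gridded_hdf5(series: GriddedSeries, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["t0"] = series.t0
        f.attrs["step"] = series.step
        for ch, v in series.channels.items():
            f.create_dataset(ch, data=v)
            f.create_dataset(ch + "__prov", data=series.provenance[ch])


def read_gridded_hdf5(path) -> GriddedSeries:
    import h5py

    with h5py.File(path, "r") as f:
        names = [k for k in f.keys() if not k.endswith("__prov")]
        channels = {c: f[c][:] for c in names}
        prov = {c: f[c + "__prov"][:].astype(np.int8) for c in names}
        return GriddedSeries(t0=int(f.attrs["t0"]), channels=channels,
                             provenance=prov, step=int(f.attrs["step"]))


def load_schema(path) -> dict:
    """Read a YAML column-map config (source column -> canonical name)."""
    with open(path) as f:
        return yaml.safe_load(f)
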