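"""Readers and writers for the pipeline's file dialects.

Tables are plain CSV. Tracking tables are accepted in two dialects,
auto-detected: a flat header (``frame, LF_x, LF_y, LF_likelihood, ...``)
and the three-row pose-tracking header (scorer / bodyparts / coords) used
by DeepLabCut-style exports. Physiological tables carry ``time`` plus any
subset of ``flow``, ``ecg``, ``activity``, ``stim``. Event tables are tidy
one-row-per-event records. Positions may be stored in pixels; a
``meters_per_px`` scale converts to SI on read (all internal computation
is in meters and seconds, 0-referenced to recording start).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import MARKERS, PhysioRecording, TrackedTrial

__all__ = [
    "read_tracking_table",
    "write_tracking_table",
    "read_physio_table",
    "write_physio_table",
    "write_event_tables",
    "read_event_table",
    "load_config",
    "save_config",
]


# ---------------------------------------------------------------------------
# Tracking tables
# ---------------------------------------------------------------------------

def write_tracking_table(
    trial: TrackedTrial,
    path: str | Path,
    dialect: str = "flat",
    meters_per_px: float = 1.0,
) -> None:
    """Write a trial as CSV in the flat or three-row-header dialect."""
    path = Path(path)
    markers = list(trial.positions)
    if dialect == "flat":
        data: dict[str, np.ndarray] = {"frame": np.arange(trial.n_frames)}
        for m in markers:
            data[f"{m}_x"] = trial.positions[m][:, 0] / meters_per_px
            data[f"{m}_y"] = trial.positions[m][:, 1] / meters_per_px
            if trial.likelihood and m in trial.likelihood:
                data[f"{m}_likelihood"] = trial.likelihood[m]
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
    elif dialect == "dlc":
        cols = pd.MultiIndex.from_tuples(
            [("model", m, c) for m in markers for c in ("x", "y", "likelihood")],
            names=["scorer", "bodyparts", "coords"],
        )
        arr = np.empty((trial.n_frames, len(cols)))
        for i, m in enumerate(markers):
            arr[:, 3 * i] = trial.positions[m][:, 0] / meters_per_px
            arr[:, 3 * i + 1] = trial.positions[m][:, 1] / meters_per_px
            lk = (trial.likelihood or {}).get(m, np.ones(trial.n_frames))
            arr[:, 3 * i + 2] = lk
        df = pd.DataFrame(arr, columns=cols)
        df.index.name = None
        df.to_csv(path, float_format="%.12g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _detect_dialect(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "dlc" if first.split(",")[0].strip().lower() == "scorer" else "flat"


def read_tracking_table(
    path: str | Path,
    frame_rate: float,
    light_onset: float,
    light_offset: float,
    marker_map: dict[str, str] | None = None,
    meters_per_px: float = 1.0,
    required_markers: tuple[str, ...] = MARKERS,
) -> TrackedTrial:
    """Read a tracking table (either dialect) into a TrackedTrial.

    ``marker_map`` renames file marker names to the canonical ones
    (e.g. ``{"left_fore": "LF"}``). Raises a descriptive error naming any
    missing required marker; a non-uniform frame index is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _detect_dialect(path)

    positions: dict[str, np.ndarray] = {}
    likelihood: dict[str, np.ndarray] = {}
    if dialect == "flat":
        df = pd.read_csv(path)
        if "frame" in df.columns:
            idx = df["frame"].to_numpy()
            if len(idx) > 1 and not np.all(np.diff(idx) == idx[1] - idx[0]):
                raise ValueError("non-uniform frame index")
        found = {c[:-2] for c in df.columns if c.endswith("_x")}
        for name in found:
            canon = (marker_map or {}).get(name, name)
            positions[canon] = np.column_stack(
                [df[f"{name}_x"].to_numpy(), df[f"{name}_y"].to_numpy()]
            ) * meters_per_px
            if f"{name}_likelihood" in df.columns:
                likelihood[canon] = df[f"{name}_likelihood"].to_numpy()
    else:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        idx = df.index.to_numpy().astype(float)
        if len(idx) > 1 and not np.all(np.diff(idx) == idx[1] - idx[0]):
            raise ValueError("non-uniform frame index")
        for name in df.columns.get_level_values("bodyparts").unique():
            canon = (marker_map or {}).get(name, name)
            sub = df.xs(name, axis=1, level="bodyparts")
            sub.columns = sub.columns.get_level_values("coords")
            positions[canon] = np.column_stack(
                [sub["x"].to_numpy(), sub["y"].to_numpy()]
            ) * meters_per_px
            if "likelihood" in sub.columns:
                likelihood[canon] = sub["likelihood"].to_numpy()

    missing = [m for m in required_markers if m not in positions]
    if missing:
        raise ValueError(
            f"tracking table {path.name} is missing required marker(s): "
            + ", ".join(missing))
    for name, lk in likelihood.items():
        if np.any((lk < 0) | (lk > 1)):
            raise ValueError(f"likelihood for {name!r} outside [0, 1]")
    return TrackedTrial(
        positions=positions, frame_rate=frame_rate,
        light_onset=light_onset, light_offset=light_offset,
        likelihood=likelihood or None,
    )


# ---------------------------------------------------------------------------
# Physiological tables
# ---------------------------------------------------------------------------

_PHYSIO_SIGNALS = ("flow", "ecg", "activity", "stim")


def write_physio_table(rec: PhysioRecording, path: str | Path) -> None:
    data: dict[str, np.ndarray] = {"time": rec.times}
    for name in _PHYSIO_SIGNALS:
        trace = getattr(rec, name)
        if trace is not None:
            data[name] = trace
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_physio_table(
    path: str | Path,
    expected_sample_rate: float | None = None,
) -> PhysioRecording:
    """Read an exported physiological ASCII/CSV table.

    Requires ``time`` plus at least one signal column. The sample rate is
    inferred from the time stamps; if it disagrees with
    ``expected_sample_rate`` by more than 0.1%, reading is refused (no
    implicit resampling) after emitting a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path.name} is empty")
    if "time" not in df.columns:
        raise ValueError(f"{path.name} has no 'time' column")
    present = [c for c in _PHYSIO_SIGNALS if c in df.columns]
    if not present:
        raise ValueError(f"{path.name} carries no signal columns")
    t = df["time"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("non-monotonic time column")
        sr = 1.0 / float(np.median(dt))
    else:
        sr = expected_sample_rate or 1000.0
    if expected_sample_rate is not None and \
            abs(sr - expected_sample_rate) > 1e-3 * expected_sample_rate:
        warnings.warn(
            f"sample rate {sr:.6g} Hz in {path.name} does not match the "
            f"configured {expected_sample_rate:.6g} Hz; refusing to resample")
        raise ValueError("sampling-rate mismatch")
    kw = {name: df[name].to_numpy(dtype=float) for name in present}
    return PhysioRecording(sample_rate=sr, **kw)


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

_EVENT_LEAD_COLS = ["type", "onset", "offset"]


def write_event_tables(events: list[dict], path: str | Path) -> None:
    """Write a tidy one-row-per-event table.

    Each event is a mapping with at least ``type`` and ``onset`` (and
    usually ``offset``); metric columns form a stable superset across
    mixed event types, ordered lead columns first then alphabetically.
    An empty list produces a header-only file.
    """
    extra = sorted({k for ev in events for k in ev} - set(_EVENT_LEAD_COLS))
    cols = _EVENT_LEAD_COLS + extra
    df = pd.DataFrame(events, columns=cols)
    df.to_csv(path, index=False, float_format="%.12g")


def read_event_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def save_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
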