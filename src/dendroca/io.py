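"""Readers and writers for the formats the pipeline consumes.

Multi-page TIFF for image stacks (frame rate carried in the TIFF's shaped
metadata), comma-delimited text with a header for traces, behavior logs,
event tables and shift series, and JSON for simulation configs. All writers
produce files their readers parse back identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import BehaviorLog
from .synthetic import SimConfig

__all__ = [
    "ImageStack",
    "TraceTable",
    "read_stack",
    "write_stack",
    "read_behavior",
    "write_behavior",
    "read_traces",
    "write_traces",
    "read_shifts",
    "write_shifts",
    "read_events",
    "write_events",
    "read_config",
    "write_config",
    "read_label_image",
    "write_label_image",
]

BEHAVIOR_EVENT_TYPES = ("cue_onset", "cue_offset", "water", "lick")


@dataclass
class ImageStack:
    """A time-series image stack with its frame rate and channel label."""

    frames: np.ndarray  # (T, H, W)
    frame_rate: float
    channel: str = "green"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class TraceTable:
    """Per-ROI fluorescence traces of equal length at one frame rate."""

    traces: pd.DataFrame  # one column per roi_id, one row per frame
    frame_rate: float

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def roi_ids(self) -> list[str]:
        return list(self.traces.columns)

    def trace(self, roi_id) -> np.ndarray:
        return self.traces[roi_id].to_numpy(dtype=float)


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as multi-page TIFF; frame rate goes into the metadata."""
    tifffile.imwrite(
        str(path),
        stack.frames,
        metadata={"frame_rate": stack.frame_rate, "channel": stack.channel},
    )


def read_stack(path, frame_rate: float | None = None, channel: str | None = None) -> ImageStack:
    """Read a multi-page TIFF stack.

    The frame rate is taken from the file's metadata when present; for
    foreign files without it, ``frame_rate`` is a required argument. Pages
    with mismatched dimensions are a format error (tifffile refuses to
    stack them).
    """
    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError("TIFF pages do not form a (T, H, W) stack")
    fr = meta.get("frame_rate", frame_rate)
    if fr is None:
        raise ValueError(
            "no frame-rate metadata in file; pass frame_rate explicitly"
        )
    ch = channel or meta.get("channel", "green")
    return ImageStack(frames=frames, frame_rate=float(fr), channel=ch)


def write_behavior(path, log: BehaviorLog) -> None:
    """Write a behavior log as delimited text with columns event_type,time_s."""
    rows = []
    for name, times in (
        ("cue_onset", log.cue_onsets),
        ("cue_offset", log.cue_offsets),
        ("water", log.water_times),
        ("lick", log.lick_times),
    ):
        rows += [(name, float(t)) for t in times]
    rows.sort(key=lambda r: (r[1], r[0]))
    df = pd.DataFrame(rows, columns=["event_type", "time_s"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_behavior(path) -> BehaviorLog:
    """Read a two-column (event_type, time_s) behavior log.

    Unknown event types, non-finite, negative, or per-type unsorted
    timestamps are rejected.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return BehaviorLog()
    if df.empty:
        return BehaviorLog()
    if list(df.columns) != ["event_type", "time_s"]:
        raise ValueError("behavior log must have columns event_type,time_s")
    unknown = set(df["event_type"]) - set(BEHAVIOR_EVENT_TYPES)
    if unknown:
        raise ValueError(f"unknown behavior event types: {sorted(unknown)}")
    vals = {}
    for name in BEHAVIOR_EVENT_TYPES:
        t = df.loc[df["event_type"] == name, "time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError(f"{name} timestamps are unsorted")
        vals[name] = t
    return BehaviorLog(
        cue_onsets=vals["cue_onset"],
        cue_offsets=vals["cue_offset"],
        water_times=vals["water"],
        lick_times=vals["lick"],
    )


def write_traces(path, table: TraceTable) -> None:
    """Write a trace table as CSV; the frame rate rides in a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz={table.frame_rate!r}\n")
        table.traces.to_csv(fh, index=False, float_format="%.17g")


def read_traces(path) -> TraceTable:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# frame_rate_hz="):
            raise ValueError("trace table missing frame-rate comment line")
        fr = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, float_precision="round_trip")
    arr = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("trace table contains non-finite samples")
    return TraceTable(traces=df, frame_rate=fr)


def write_shifts(path, shifts: np.ndarray) -> None:
    """Write a per-frame shift series as CSV (frame, dx, dy)."""
    shifts = np.asarray(shifts, dtype=float)
    df = pd.DataFrame(
        {"frame": np.arange(shifts.shape[0]), "dx": shifts[:, 0], "dy": shifts[:, 1]}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_shifts(path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    out = df[["dx", "dy"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(out)):
        raise ValueError("shift series contains non-finite values")
    return out


def write_events(path, events: pd.DataFrame) -> None:
    """Write an event table (roi_id, time_s, peak_dff, isolation, epoch, ...)."""
    events.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" in df and np.any(df["time_s"] < 0):
        raise ValueError("event times must be non-negative")
    return df


def write_config(path, config: SimConfig) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def read_config(path) -> SimConfig:
    return SimConfig.from_dict(json.loads(Path(path).read_text()))


def write_label_image(path, label_image: np.ndarray) -> None:
    """Write ROI masks as a labeled-integer TIFF."""
    tifffile.imwrite(str(path), np.asarray(label_image, dtype=np.int32))


def read_label_image(path) -> np.ndarray:
    return tifffile.imread(str(path))
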