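"""Readers and writers for the pipeline's on-disk formats.

Everything external is plain text: tidy TSV trace tables (axon_id,
channel, time_h, intensity), one-row-per-axon schedule/call tables with
empty fields for missing events, track tables (axon_id, bout_start_h,
track_id, frame, position_um), and 8-bit grayscale TIFF/PNG images whose
filenames carry a parseable time token (``..._t{hours}h``).  Hours are
the external time unit throughout; decimal separator is '.'.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .cascade import EVENT_ORDER, EventSchedule
from .events import EventCalls
from .simulate import AxonImage, AxonTraceSet, Cohort, KymographBout, MitoTrack

TRACE_COLUMNS = ["axon_id", "channel", "time_h", "intensity"]
TRACK_COLUMNS = ["axon_id", "bout_start_h", "track_id", "frame", "position_um"]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def write_traces(traces: Sequence[AxonTraceSet], path) -> None:
    rows = []
    for ts in traces:
        for channel, (t, v) in ts.channels.items():
            for ti, vi in zip(t, v):
                rows.append((ts.axon_id, channel, float(ti), float(vi)))
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_traces(path, baseline_window=(-0.5, 0.0)) -> list[AxonTraceSet]:
    """Read and validate a tidy trace table.

    Malformed rows (non-monotone time, negative intensity) are reported
    with their 1-based data row numbers.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if (df["intensity"] < 0).any():
        rows = (df.index[df["intensity"] < 0] + 2).tolist()
        raise FormatError(f"{path}: negative intensity at file row(s) {rows[:5]}")
    out = []
    for axon_id, adf in df.groupby("axon_id", sort=True):
        channels = {}
        for channel, cdf in adf.groupby("channel", sort=True):
            t = cdf["time_h"].to_numpy(dtype=float)
            bad = np.nonzero(np.diff(t) <= 0)[0]
            if bad.size:
                row = int(cdf.index[bad[0] + 1]) + 2
                raise FormatError(
                    f"{path}: non-monotone time for axon {axon_id!r} channel "
                    f"{channel!r} at file row {row}"
                )
            channels[channel] = (t, cdf["intensity"].to_numpy(dtype=float))
        out.append(
            AxonTraceSet(
                axon_id=str(axon_id), channels=channels, baseline_window=baseline_window
            )
        )
    return out


def _times_frame(records: Sequence[dict], columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_records(records, columns=columns)


def write_schedules(schedules: Sequence[EventSchedule], path) -> None:
    cols = ["axon_id", "t_injury", *EVENT_ORDER]
    _times_frame([s.as_dict() for s in schedules], cols).to_csv(
        path, sep="\t", index=False
    )


def read_schedules(path) -> list[EventSchedule]:
    df = pd.read_csv(path, sep="\t")
    if "axon_id" not in df.columns:
        raise FormatError(f"{path}: missing axon_id column")
    out = []
    for _, row in df.iterrows():
        kwargs = {"axon_id": str(row["axon_id"])}
        for name in EVENT_ORDER:
            if name in df.columns and not (
                isinstance(row[name], float) and math.isnan(row[name])
            ):
                kwargs[name] = float(row[name])
        out.append(EventSchedule(**kwargs))
    return out


def write_calls(calls: Sequence[EventCalls], path) -> None:
    keys = sorted({k for c in calls for k in c.times})
    rows = []
    for c in calls:
        row = {"axon_id": c.axon_id}
        for k in keys:
            row[k] = c.times.get(k)
        row["qc_flags"] = ";".join(sorted(c.qc_flags))
        rows.append(row)
    pd.DataFrame(rows, columns=["axon_id", *keys, "qc_flags"]).to_csv(
        path, sep="\t", index=False
    )


def read_calls(path) -> list[EventCalls]:
    df = pd.read_csv(path, sep="\t")
    if "axon_id" not in df.columns:
        raise FormatError(f"{path}: missing axon_id column")
    event_cols = [c for c in df.columns if c not in ("axon_id", "qc_flags")]
    out = []
    for _, row in df.iterrows():
        c = EventCalls(axon_id=str(row["axon_id"]))
        for k in event_cols:
            val = row[k]
            c.times[k] = None if (isinstance(val, float) and math.isnan(val)) else float(val)
        flags = row.get("qc_flags")
        if isinstance(flags, str) and flags:
            c.qc_flags = set(flags.split(";"))
        out.append(c)
    return out


def write_tracks(bouts_per_axon: dict[str, Sequence[KymographBout]], path) -> None:
    rows = []
    for axon_id, bouts in bouts_per_axon.items():
        for bout in bouts:
            for track in bout.tracks:
                for frame, pos in enumerate(track.positions_um):
                    rows.append(
                        (axon_id, bout.bout_start, track.track_id, frame, float(pos))
                    )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


def read_tracks(path, frame_interval_s: float = 5.0) -> dict[str, list[KymographBout]]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out: dict[str, list[KymographBout]] = {}
    for (axon_id, start), bdf in df.groupby(["axon_id", "bout_start_h"], sort=True):
        tracks = []
        for tid, tdf in bdf.groupby("track_id", sort=True):
            tdf = tdf.sort_values("frame")
            tracks.append(
                MitoTrack(
                    track_id=int(tid),
                    positions_um=tdf["position_um"].to_numpy(dtype=float),
                )
            )
        n_frames = max(len(t.positions_um) for t in tracks)
        out.setdefault(str(axon_id), []).append(
            KymographBout(
                bout_start=float(start),
                frame_interval=frame_interval_s,
                n_frames=n_frames,
                tracks=tracks,
            )
        )
    for bouts in out.values():
        bouts.sort(key=lambda b: b.bout_start)
    return out


_TIME_TOKEN = re.compile(r"t(-?\d+(?:\.\d+)?)h")


def image_filename(prefix: str, time_h: float, ext: str = "tif") -> str:
    return f"{prefix}_t{time_h:.2f}h.{ext}"


def write_images(images: Sequence[AxonImage], directory, prefix: str = "axon") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for img in images:
        p = directory / image_filename(prefix, img.time)
        iio.imwrite(p, img.pixels)
        paths.append(p)
    return paths


def read_images(directory, pixel_size: float = 0.3) -> list[AxonImage]:
    """Load a time-indexed image series from TIFF/PNG files whose names
    carry a ``t{hours}h`` token; returns images sorted by time."""
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
    )
    if not files:
        raise FormatError(f"{directory}: no TIFF/PNG images found")
    images = []
    shape = None
    for p in files:
        m = _TIME_TOKEN.search(p.stem)
        if not m:
            raise FormatError(f"{p.name}: no parseable time token (expected t<h>h)")
        pixels = np.asarray(iio.imread(p))
        if shape is None:
            shape = pixels.shape
        elif pixels.shape != shape:
            raise FormatError(
                f"{p.name}: image dimensions {pixels.shape} differ from {shape}"
            )
        images.append(
            AxonImage(time=float(m.group(1)), pixels=pixels, pixel_size=pixel_size)
        )
    images.sort(key=lambda im: im.time)
    return images


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write a simulated cohort to disk in the external formats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": out_dir / "traces.tsv",
        "schedules": out_dir / "schedules.tsv",
        "tracks": out_dir / "tracks.tsv",
    }
    write_traces(cohort.traces, paths["traces"])
    write_schedules(cohort.schedules, paths["schedules"])
    write_tracks(
        {s.axon_id: b for s, b in zip(cohort.schedules, cohort.bouts) if b},
        paths["tracks"],
    )
    for sched, images in zip(cohort.schedules, cohort.images):
        if images:
            write_images(images, out_dir / "images", prefix=sched.axon_id)
    return paths
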