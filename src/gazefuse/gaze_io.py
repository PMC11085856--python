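"""Gaze-export ingestion and video/frame bookkeeping.

Wearable eye trackers export gaze as delimited text with one row per sample:
a timestamp plus normalized scene-camera coordinates (and sometimes the frame
index the device already synchronized). This module reads those exports into
:class:`GazeRecording`, maps timestamps onto video frame indices, converts
normalized coordinates to pixels and extracts frames from a video container or
a directory of numbered images.

Coordinate convention: the normalized origin is the top-left corner of the
scene camera, x grows rightward and y grows downward (the common export
convention). Exports whose y axis points up are handled by ``y_axis="up"`` at
load time, which flips y to the internal convention.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, RangeError

logger = logging.getLogger(__name__)

__all__ = [
    "GazeSample",
    "VideoMeta",
    "GazeRecording",
    "load_gaze_csv",
    "write_gaze_csv",
    "frame_index_for_time",
    "pixel_from_norm",
    "extract_frames",
]


@dataclass(frozen=True)
class GazeSample:
    """One gaze sample: time in seconds and normalized scene coordinates."""

    t: float
    x_norm: float
    y_norm: float
    frame_index: int | None = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise DataError(f"sample time must be >= 0, got {self.t}")
        if not (0.0 <= self.x_norm <= 1.0 and 0.0 <= self.y_norm <= 1.0):
            raise DataError(
                f"normalized coordinates out of [0,1]: ({self.x_norm}, {self.y_norm})"
            )
        if self.frame_index is not None and self.frame_index < 0:
            raise DataError(f"frame_index must be >= 0, got {self.frame_index}")


@dataclass(frozen=True)
class VideoMeta:
    """Scene-video geometry and timing.

    Either ``duration`` or ``n_frames`` may be derived from the other; when
    both are supplied they must agree to within one frame.
    """

    width: int
    height: int
    fps: float
    duration: float = None  # type: ignore[assignment]
    n_frames: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ConfigError("frame dimensions must be >= 1 pixel")
        if self.fps <= 0:
            raise ConfigError(f"fps must be positive, got {self.fps}")
        if self.duration is None and self.n_frames is None:
            raise ConfigError("VideoMeta needs duration and/or n_frames")
        if self.n_frames is None:
            object.__setattr__(self, "n_frames", int(round(self.duration * self.fps)))
        if self.duration is None:
            object.__setattr__(self, "duration", self.n_frames / self.fps)
        if self.duration < 0 or self.n_frames < 0:
            raise ConfigError("duration and n_frames must be non-negative")
        if abs(self.n_frames - self.duration * self.fps) > 1.0 + 1e-9:
            raise ConfigError(
                f"n_frames={self.n_frames} inconsistent with "
                f"duration*fps={self.duration * self.fps:.3f}"
            )


@dataclass
class GazeRecording:
    """An ordered gaze stream plus the metadata of the scene video."""

    samples: list[GazeSample]
    rate_hz: float
    meta: VideoMeta

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ConfigError(f"rate_hz must be positive, got {self.rate_hz}")
        times = [s.t for s in self.samples]
        if any(b < a for a, b in zip(times, times[1:])):
            raise DataError("samples must be sorted by time")

    def __len__(self) -> int:
        return len(self.samples)

    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples], dtype=float)

    def xy(self) -> np.ndarray:
        """(n, 2) array of normalized coordinates."""
        return np.array([(s.x_norm, s.y_norm) for s in self.samples], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": [s.t for s in self.samples],
                "x_norm": [s.x_norm for s in self.samples],
                "y_norm": [s.y_norm for s in self.samples],
                "frame_index": [s.frame_index for s in self.samples],
            }
        )


DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "t": "t",
    "x_norm": "x_norm",
    "y_norm": "y_norm",
    "frame_index": "frame_index",
}


def load_gaze_csv(
    path: str | Path,
    meta: VideoMeta,
    rate_hz: float,
    column_map: Mapping[str, str] | None = None,
    clamp_policy: str = "clamp",
    y_axis: str = "down",
) -> GazeRecording:
    """Read a delimited gaze export into a :class:`GazeRecording`.

    Parameters
    ----------
    path
        CSV/TSV file; the delimiter is sniffed.
    column_map
        Maps the canonical field names (``t``, ``x_norm``, ``y_norm`` and
        optionally ``frame_index``) to the column names in the file.
    clamp_policy
        How to treat coordinates outside [0, 1]: ``clamp`` (default; trackers
        emit slightly out-of-frame samples during blinks), ``drop``, or
        ``error``. Under ``error`` non-monotone timestamps are also fatal;
        otherwise rows are sorted by time.
    y_axis
        ``down`` (internal convention) or ``up`` (flip y at load).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if clamp_policy not in ("clamp", "drop", "error"):
        raise ConfigError(f"unknown clamp_policy {clamp_policy!r}")
    if y_axis not in ("down", "up"):
        raise ConfigError(f"unknown y_axis {y_axis!r}")

    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    import csv as _csv

    with open(path, encoding="utf-8", newline="") as fh:
        sample = fh.read(8192)
    try:
        delim = _csv.Sniffer().sniff(sample, delimiters=",;\t ").delimiter
    except _csv.Error:
        delim = ","
    # C engine + round_trip parsing keeps coordinates bit-exact through I/O
    df = pd.read_csv(path, sep=delim, float_precision="round_trip")
    for key in ("t", "x_norm", "y_norm"):
        if cmap[key] not in df.columns:
            raise ConfigError(
                f"gaze file {path.name} lacks required column {cmap[key]!r} "
                f"(mapped from {key!r})"
            )
    have_frame = cmap.get("frame_index") in df.columns

    t = pd.to_numeric(df[cmap["t"]], errors="raise").to_numpy(dtype=float)
    x = pd.to_numeric(df[cmap["x_norm"]], errors="raise").to_numpy(dtype=float)
    y = pd.to_numeric(df[cmap["y_norm"]], errors="raise").to_numpy(dtype=float)
    if y_axis == "up":
        y = 1.0 - y
    frames = (
        pd.to_numeric(df[cmap["frame_index"]], errors="raise").to_numpy(dtype=float)
        if have_frame
        else None
    )
    if frames is not None and np.isnan(frames).all():  # present but empty column
        frames = None

    non_monotone = np.flatnonzero(np.diff(t) < 0)
    if non_monotone.size:
        if clamp_policy == "error":
            raise DataError(
                f"non-monotone timestamps: row {int(non_monotone[0]) + 1} "
                f"goes backwards"
            )
        order = np.argsort(t, kind="stable")
        t, x, y = t[order], x[order], y[order]
        if frames is not None:
            frames = frames[order]
        logger.warning("gaze rows re-sorted by time (%d inversions)", non_monotone.size)

    out_of_range = (x < 0) | (x > 1) | (y < 0) | (y > 1)
    n_bad = int(out_of_range.sum())
    if n_bad:
        if clamp_policy == "error":
            first = int(np.flatnonzero(out_of_range)[0])
            raise DataError(f"coordinate out of [0,1] at row {first}")
        if clamp_policy == "clamp":
            x = np.clip(x, 0.0, 1.0)
            y = np.clip(y, 0.0, 1.0)
            logger.warning("clamped %d out-of-range gaze samples", n_bad)
        else:  # drop
            keep = ~out_of_range
            t, x, y = t[keep], x[keep], y[keep]
            if frames is not None:
                frames = frames[keep]
            logger.warning("dropped %d out-of-range gaze samples", n_bad)

    samples = [
        GazeSample(
            t=float(ti),
            x_norm=float(xi),
            y_norm=float(yi),
            frame_index=(
                int(frames[i]) if frames is not None and not math.isnan(frames[i]) else None
            ),
        )
        for i, (ti, xi, yi) in enumerate(zip(t, x, y))
    ]
    return GazeRecording(samples=samples, rate_hz=rate_hz, meta=meta)


def write_gaze_csv(rec: GazeRecording, path: str | Path) -> Path:
    """Write a recording back to CSV at full float precision (round-trips)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("t,x_norm,y_norm,frame_index\n")
        for s in rec.samples:
            fi = "" if s.frame_index is None else str(s.frame_index)
            fh.write(f"{float(s.t)!r},{float(s.x_norm)!r},{float(s.y_norm)!r},{fi}\n")
    return path


def frame_index_for_time(t: float, meta: VideoMeta) -> int:
    """Map a timestamp to the video frame shown at that instant.

    Returns ``floor(t * fps)`` capped at ``n_frames - 1`` (the last frame is
    on screen through the video's final instant).
    """
    if not (0.0 <= t <= meta.duration):
        raise RangeError(f"time {t} outside [0, {meta.duration}]")
    return min(int(math.floor(t * meta.fps)), meta.n_frames - 1)


def pixel_from_norm(
    x_norm: float, y_norm: float, width: int, height: int
) -> tuple[int, int]:
    """Normalized [0,1] coordinates -> integer pixel, total on the closed unit square.

    Sub-pixel positions are floored; x_norm == 1.0 maps to the last column so
    the mapping never leaves the frame.
    """
    px = min(int(math.floor(x_norm * width)), width - 1)
    py = min(int(math.floor(y_norm * height)), height - 1)
    return px, py


_FRAME_NAME_RE = re.compile(r"(\d+)\.(?:png|jpg|jpeg)$", re.IGNORECASE)


def _frame_files(directory: Path) -> dict[int, Path]:
    found: dict[int, Path] = {}
    for p in sorted(directory.iterdir()):
        m = _FRAME_NAME_RE.search(p.name)
        if m:
            found[int(m.group(1))] = p
    return found


def extract_frames(
    source: str | Path | Mapping[int, np.ndarray],
    indices: Iterable[int],
    meta: VideoMeta | None = None,
) -> dict[int, np.ndarray]:
    """Fetch the requested frames from a video file, a frame directory, or a mapping.

    Directories must contain images named by (zero-padded) frame index, e.g.
    ``frame_000042.png`` or ``42.png``. Indices that cannot be decoded raise;
    nothing is skipped silently.
    """
    wanted = sorted(set(int(i) for i in indices))
    if meta is not None:
        for i in wanted:
            if i < 0 or i >= meta.n_frames:
                raise RangeError(f"frame index {i} outside [0, {meta.n_frames})")
    if not wanted:
        return {}

    if isinstance(source, Mapping):
        missing = [i for i in wanted if i not in source]
        if missing:
            raise RangeError(f"frames not available in mapping: {missing[:5]}")
        return {i: np.asarray(source[i]) for i in wanted}

    source = Path(source)
    if source.is_dir():
        files = _frame_files(source)
        missing = [i for i in wanted if i not in files]
        if missing:
            raise RangeError(f"frame files missing in {source}: {missing[:5]}")
        import imageio.v3 as iio

        return {i: np.asarray(iio.imread(files[i])) for i in wanted}

    # Video container: decodable only where an imageio plugin exists.
    try:
        import imageio.v3 as iio

        out: dict[int, np.ndarray] = {}
        for i in wanted:
            out[i] = np.asarray(iio.imread(source, index=i))
        return out
    except RangeError:
        raise
    except Exception as exc:  # plugin/codec failures surface as I/O errors
        raise IOError(f"cannot decode frames from {source}: {exc}") from exc
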