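"""Dispersion-threshold (IDT) fixation detection.

IDT groups consecutive gaze samples whose spatial dispersion — here
``(max x - min x) + (max y - min y)`` over the window, per the classic
formulation — stays below a threshold for at least a minimum duration
(default 100 ms). Each emitted fixation carries the centroid of its member
samples, its dispersion, and a representative video frame taken at the
temporal midpoint of the fixation (midpoint avoids the motion blur typical
of fixation onset after a saccade).

The dispersion threshold may be given in normalized scene-camera units or in
visual degrees; degrees are converted isotropically via the horizontal field
of view (``threshold_norm = threshold_deg / fov_deg``). The default threshold
is 0.02 degrees with a 100 ms minimum duration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .gaze_io import GazeRecording, GazeSample, VideoMeta, frame_index_for_time

__all__ = [
    "Fixation",
    "IdtConfig",
    "dispersion",
    "detect_fixations_idt",
    "assign_frame",
    "write_fixations_csv",
    "read_fixations_csv",
]


@dataclass(frozen=True)
class Fixation:
    """A dispersion-bounded gaze cluster."""

    t_start: float
    t_end: float
    centroid_x: float
    centroid_y: float
    dispersion: float
    n_samples: int
    frame_index: int | None = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass(frozen=True)
class IdtConfig:
    """IDT parameters.

    ``dispersion_threshold`` is interpreted in ``unit`` ("normalized" or
    "degrees"); degrees require ``fov_deg``, the scene camera's horizontal
    field of view.
    """

    dispersion_threshold: float = 0.02
    unit: str = "degrees"
    duration_threshold: float = 0.100
    fov_deg: float | None = None

    def __post_init__(self) -> None:
        if self.dispersion_threshold <= 0:
            raise ConfigError("dispersion_threshold must be positive")
        if self.duration_threshold <= 0:
            raise ConfigError("duration_threshold must be positive")
        if self.unit not in ("normalized", "degrees"):
            raise ConfigError(f"unknown dispersion unit {self.unit!r}")

    def threshold_normalized(self) -> float:
        """Dispersion threshold in normalized units."""
        if self.unit == "normalized":
            return self.dispersion_threshold
        if self.fov_deg is None or self.fov_deg <= 0:
            raise ConfigError(
                "unit='degrees' requires fov_deg (horizontal field of view)"
            )
        return self.dispersion_threshold / self.fov_deg


def dispersion(window: Sequence[GazeSample] | np.ndarray) -> float:
    """(max x - min x) + (max y - min y) over a non-empty sample window."""
    if len(window) == 0:
        raise ValueError("dispersion of an empty window is undefined")
    if isinstance(window, np.ndarray):
        xy = np.asarray(window, dtype=float)
    else:
        xy = np.array([(s.x_norm, s.y_norm) for s in window], dtype=float)
    return float(
        (xy[:, 0].max() - xy[:, 0].min()) + (xy[:, 1].max() - xy[:, 1].min())
    )


def detect_fixations_idt(rec: GazeRecording, cfg: IdtConfig) -> list[Fixation]:
    """Classic IDT sweep over a recording.

    Initialize a window spanning ``duration_threshold``; if its dispersion is
    within threshold, grow it sample-by-sample while dispersion stays within
    threshold, emit a fixation, and resume after the window; otherwise slide
    the window start by one sample. Emitted fixations are disjoint in time
    and ordered. Fewer samples than span the duration threshold yield an
    empty result.
    """
    thresh = cfg.threshold_normalized()
    n = len(rec.samples)
    if n < 2:
        return []
    t = rec.times()
    xy = rec.xy()

    fixations: list[Fixation] = []
    i = 0
    while i < n:
        # smallest j with t[j] - t[i] >= duration_threshold
        j = int(np.searchsorted(t, t[i] + cfg.duration_threshold, side="left"))
        if j >= n:
            break
        win = xy[i : j + 1]
        x_min, x_max = win[:, 0].min(), win[:, 0].max()
        y_min, y_max = win[:, 1].min(), win[:, 1].max()
        if (x_max - x_min) + (y_max - y_min) <= thresh:
            while j + 1 < n:
                xn, yn = xy[j + 1]
                nx_min, nx_max = min(x_min, xn), max(x_max, xn)
                ny_min, ny_max = min(y_min, yn), max(y_max, yn)
                if (nx_max - nx_min) + (ny_max - ny_min) > thresh:
                    break
                x_min, x_max, y_min, y_max = nx_min, nx_max, ny_min, ny_max
                j += 1
            member = xy[i : j + 1]
            fixations.append(
                Fixation(
                    t_start=float(t[i]),
                    t_end=float(t[j]),
                    centroid_x=float(member[:, 0].mean()),
                    centroid_y=float(member[:, 1].mean()),
                    dispersion=float((x_max - x_min) + (y_max - y_min)),
                    n_samples=j - i + 1,
                )
            )
            i = j + 1
        else:
            i += 1
    return fixations


def assign_frame(fix: Fixation, meta: VideoMeta) -> Fixation:
    """Attach the representative frame: the one at the fixation's midpoint."""
    return replace(fix, frame_index=frame_index_for_time(fix.midpoint, meta))


_FIX_COLUMNS = [
    "t_start",
    "t_end",
    "x_norm",
    "y_norm",
    "dispersion",
    "n_samples",
    "frame_index",
]


def write_fixations_csv(fixations: Sequence[Fixation], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FIX_COLUMNS)
        for f in fixations:
            writer.writerow(
                [
                    repr(f.t_start),
                    repr(f.t_end),
                    repr(f.centroid_x),
                    repr(f.centroid_y),
                    repr(f.dispersion),
                    f.n_samples,
                    "" if f.frame_index is None else f.frame_index,
                ]
            )
    return path


def read_fixations_csv(path: str | Path) -> list[Fixation]:
    out: list[Fixation] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Fixation(
                    t_start=float(row["t_start"]),
                    t_end=float(row["t_end"]),
                    centroid_x=float(row["x_norm"]),
                    centroid_y=float(row["y_norm"]),
                    dispersion=float(row["dispersion"]),
                    n_samples=int(row["n_samples"]),
                    frame_index=int(row["frame_index"]) if row["frame_index"] else None,
                )
            )
    return out
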