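"""Annotation CSV serialization and per-frame visualization.

The annotation CSV is the pipeline's primary product: one row per fixation
with the frame index, fixation coordinates (normalized and pixel), the
segmentation label, the selected detection box with its label, confidence
and mask coverage, the resolved label, its merged form, and the resolution
branch that produced it. Optional fields serialize as empty strings; the
file round-trips byte-identically through read/write.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np

from .backends import DetectedBox, SemanticSegmentation
from .fusion import CandidateBox, FixationAnnotation
from .taxonomy import MergeMap, DEFAULT_MERGE_MAP

__all__ = ["ANNOTATION_COLUMNS", "write_annotations", "read_annotations", "render_annotation"]

ANNOTATION_COLUMNS = [
    "frame_index",
    "x_norm",
    "y_norm",
    "x_px",
    "y_px",
    "mask_label",
    "box_label",
    "coverage",
    "x1",
    "y1",
    "x2",
    "y2",
    "confidence",
    "resolved_label",
    "merged_label",
    "branch",
]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_annotations(
    annotations: Sequence[FixationAnnotation],
    path: str | Path,
    merge_map: MergeMap | None = None,
) -> Path:
    """Write one CSV row per fixation annotation (header-only when empty)."""
    merge_map = merge_map if merge_map is not None else DEFAULT_MERGE_MAP
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for a in annotations:
            box = a.box
            writer.writerow(
                [
                    a.frame_index,
                    _fmt(a.x_norm),
                    _fmt(a.y_norm),
                    a.x_px,
                    a.y_px,
                    a.mask_label,
                    _fmt(a.box_label),
                    _fmt(a.coverage),
                    _fmt(box.x1 if box else None),
                    _fmt(box.y1 if box else None),
                    _fmt(box.x2 if box else None),
                    _fmt(box.y2 if box else None),
                    _fmt(a.confidence),
                    a.resolved_label,
                    merge_map(a.resolved_label),
                    a.branch,
                ]
            )
    return path


def read_annotations(path: str | Path) -> list[FixationAnnotation]:
    out: list[FixationAnnotation] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            has_box = row["box_label"] != ""
            box = (
                DetectedBox(
                    int(row["x1"]),
                    int(row["y1"]),
                    int(row["x2"]),
                    int(row["y2"]),
                    label=row["box_label"],
                    confidence=float(row["confidence"]),
                )
                if has_box
                else None
            )
            out.append(
                FixationAnnotation(
                    frame_index=int(row["frame_index"]),
                    x_norm=float(row["x_norm"]),
                    y_norm=float(row["y_norm"]),
                    x_px=int(row["x_px"]),
                    y_px=int(row["y_px"]),
                    mask_label=row["mask_label"],
                    resolved_label=row["resolved_label"],
                    branch=int(row["branch"]),
                    box_label=row["box_label"] or None,
                    coverage=float(row["coverage"]) if row["coverage"] else None,
                    box=box,
                    confidence=float(row["confidence"]) if row["confidence"] else None,
                )
            )
    return out


# visualization styles (RGB)
_CANDIDATE_COLOR = (255, 220, 0)  # yellow
_SELECTED_COLOR = (0, 255, 255)  # cyan
_FIXATION_COLOR = (255, 0, 0)  # red
_MASK_ALPHA = 0.4


def render_annotation(
    frame: np.ndarray,
    annotation: FixationAnnotation,
    seg: SemanticSegmentation | None = None,
    candidates: Sequence[CandidateBox] | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Draw the annotation onto a copy of the frame.

    Semi-transparent overlay of the fixated mask, candidate boxes in yellow,
    the selected box in cyan (thicker), and the fixation point as a red dot;
    the resolved label is printed near the fixation. Deterministic for fixed
    inputs.
    """
    from PIL import Image, ImageDraw

    img = Image.fromarray(np.ascontiguousarray(frame[..., :3]).astype(np.uint8))
    if mask is None and seg is not None:
        from .fusion import mask_at_point

        mask = mask_at_point(seg, annotation.x_px, annotation.y_px).pixels
    if mask is not None:
        overlay = np.array(img, dtype=np.float64)
        overlay[mask] = (1 - _MASK_ALPHA) * overlay[mask] + _MASK_ALPHA * np.array(
            _SELECTED_COLOR, dtype=np.float64
        )
        img = Image.fromarray(overlay.astype(np.uint8))

    draw = ImageDraw.Draw(img)
    for cand in candidates or []:
        b = cand.box
        draw.rectangle([b.x1, b.y1, b.x2 - 1, b.y2 - 1], outline=_CANDIDATE_COLOR, width=1)
    if annotation.box is not None:
        b = annotation.box
        draw.rectangle([b.x1, b.y1, b.x2 - 1, b.y2 - 1], outline=_SELECTED_COLOR, width=2)
    r = max(2, min(frame.shape[0], frame.shape[1]) // 64)
    draw.ellipse(
        [annotation.x_px - r, annotation.y_px - r, annotation.x_px + r, annotation.y_px + r],
        fill=_FIXATION_COLOR,
    )
    draw.text(
        (min(annotation.x_px + r + 2, img.width - 1), max(annotation.y_px - r - 10, 0)),
        annotation.resolved_label,
        fill=(255, 255, 255),
    )
    return np.array(img)
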