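"""Mask-coverage fusion: the pipeline's central computation.

A fixation lands on exactly one segmentation mask (masks partition the
frame) but possibly inside several detection boxes, because boxes overlap
when objects sit close together or at different depths. The fusion step
restricts the fixated mask M to each candidate box and scores the box by
mask coverage

    C = (# mask pixels inside the box) / ((x2 - x1) * (y2 - y1)),

the fraction of the box's area occupied by the fixated object's mask. Only
boxes that contain both the fixation point and at least one mask pixel are
candidates; the box with the greatest C wins. A tight box around the fixated
object scores near 1 while a large box around a closer occluder scores low,
which is what disambiguates objects at different depths.

By default the mask is the 4-connected component of the fixated class that
contains the fixation pixel, so a distant same-class region cannot inflate
the coverage of an unrelated box; ``component_mode="class"`` uses the whole
class mask instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.measure import label as _connected_components

from .backends import DetectedBox, SemanticSegmentation
from .errors import RangeError
from .gaze_io import pixel_from_norm
from .taxonomy import ResolutionConfig, resolve_label

__all__ = [
    "BinaryMask",
    "CandidateBox",
    "FixationAnnotation",
    "mask_at_point",
    "coverage",
    "candidate_boxes",
    "select_box",
    "annotate_fixation",
]


@dataclass
class BinaryMask:
    """The fixated object's mask M (boolean height x width)."""

    pixels: np.ndarray
    source_label: str
    component_mode: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or not self.pixels.any():
            raise ValueError("mask must be 2-D with at least one true pixel")


@dataclass(frozen=True)
class CandidateBox:
    """A detection box containing the fixation, scored by mask coverage C."""

    box: DetectedBox
    coverage: float


@dataclass(frozen=True)
class FixationAnnotation:
    """The fused record for one fixation (one output CSV row).

    ``mask_label`` is always present (segmentation is total); the box fields
    are present iff some detection box contained both the fixation point and
    the mask. ``resolved_label`` is the outcome of the resolution cascade and
    ``branch`` records which cascade rule produced it.
    """

    frame_index: int
    x_norm: float
    y_norm: float
    x_px: int
    y_px: int
    mask_label: str
    resolved_label: str
    branch: int
    box_label: str | None = None
    coverage: float | None = None
    box: DetectedBox | None = None
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.box_label is not None:
            if self.coverage is None or self.confidence is None or self.box is None:
                raise ValueError("box_label requires coverage, confidence and box")
            if not self.coverage > 0:
                raise ValueError("a selected box must have positive coverage")
        if self.resolved_label not in (self.mask_label, self.box_label):
            raise ValueError("resolved_label must come from one of the two sources")


def mask_at_point(
    seg: SemanticSegmentation, x_px: int, y_px: int, component_mode: str = "component"
) -> BinaryMask:
    """The mask under a pixel: the fixated class, or its connected component.

    ``component`` keeps only the 4-connected region of the fixated class that
    contains the pixel; ``class`` keeps every pixel of that class.
    """
    h, w = seg.shape
    if not (0 <= x_px < w and 0 <= y_px < h):
        raise RangeError(f"point ({x_px},{y_px}) outside frame {w}x{h}")
    if component_mode not in ("component", "class"):
        raise ValueError(f"unknown component_mode {component_mode!r}")
    class_id = int(seg.label_map[y_px, x_px])
    pixels = seg.label_map == class_id
    if component_mode == "component":
        comps = _connected_components(pixels, connectivity=1)
        pixels = comps == comps[y_px, x_px]
    return BinaryMask(
        pixels=pixels,
        source_label=seg.vocabulary[class_id],
        component_mode=component_mode,
    )


def coverage(mask: BinaryMask, box: DetectedBox) -> float:
    """Mask coverage C of a box: mask pixels inside it over its area.

    Counted in exact integer arithmetic; only the final ratio is a float.
    """
    h, w = mask.pixels.shape
    if box.x2 > w or box.y2 > h:
        raise ValueError(f"box {box} exceeds mask dimensions {w}x{h}")
    inside = int(mask.pixels[box.y1 : box.y2, box.x1 : box.x2].sum())
    return inside / box.area


def candidate_boxes(
    boxes: Sequence[DetectedBox], x_px: int, y_px: int, mask: BinaryMask
) -> list[CandidateBox]:
    """Boxes containing both the fixation point and >= 1 mask pixel, with their C."""
    out: list[CandidateBox] = []
    for b in boxes:
        if not b.contains(x_px, y_px):
            continue
        c = coverage(mask, b)
        if c > 0:
            out.append(CandidateBox(box=b, coverage=c))
    return out


def select_box(candidates: Sequence[CandidateBox]) -> CandidateBox | None:
    """The candidate with the greatest coverage.

    Ties break deterministically: higher confidence, then smaller area, then
    lowest (x1, y1) lexicographically.
    """
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda c: (
            -c.coverage,
            -c.box.confidence,
            c.box.area,
            c.box.x1,
            c.box.y1,
        ),
    )


def annotate_fixation(
    frame_index: int,
    x_norm: float,
    y_norm: float,
    seg: SemanticSegmentation,
    boxes: Sequence[DetectedBox],
    resolution: ResolutionConfig | None = None,
    component_mode: str = "component",
) -> FixationAnnotation:
    """Fuse both perception outputs into the final annotation for one fixation.

    Always yields a non-empty ``resolved_label``: the segmentation is total,
    so a fixation can never be 'background-only'.
    """
    resolution = resolution or ResolutionConfig()
    h, w = seg.shape
    x_px, y_px = pixel_from_norm(x_norm, y_norm, w, h)
    mask = mask_at_point(seg, x_px, y_px, component_mode)
    selected = select_box(candidate_boxes(boxes, x_px, y_px, mask))

    box_label = selected.box.label if selected else None
    cov = selected.coverage if selected else None
    conf = selected.box.confidence if selected else None
    resolved, branch = resolve_label(mask.source_label, box_label, cov, conf, resolution)
    return FixationAnnotation(
        frame_index=frame_index,
        x_norm=x_norm,
        y_norm=y_norm,
        x_px=x_px,
        y_px=y_px,
        mask_label=mask.source_label,
        resolved_label=resolved,
        branch=branch,
        box_label=box_label,
        coverage=cov,
        box=selected.box if selected else None,
        confidence=conf,
    )
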