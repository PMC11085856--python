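"""Perception contracts: dense semantic segmentation and box-level detection.

Two independent models look at each fixated frame. The segmenter partitions
the frame into non-overlapping class masks (every pixel gets exactly one
label, so a fixation is always inside exactly one mask). The detector returns
labeled rectangles with confidences; boxes may overlap freely, especially for
objects that are nearby or at different depths.

The synthetic backend renders scenes deterministically and is the one used in
tests; adapters to pretrained networks plug in behind the same contracts but
are optional and excluded from the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import CapabilityError, ConfigError

__all__ = [
    "SemanticSegmentation",
    "DetectedBox",
    "PerceptionResult",
    "PerceptionBackend",
    "SyntheticBackend",
    "load_adapter",
]


@dataclass
class SemanticSegmentation:
    """A dense per-pixel class labeling.

    ``label_map`` holds integer class ids; ``vocabulary`` maps each id to its
    class name. Masks partition the frame: exactly one id per pixel.
    """

    label_map: np.ndarray
    vocabulary: dict[int, str]

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if self.label_map.ndim != 2:
            raise ConfigError("label_map must be 2-D (height x width)")
        present = set(np.unique(self.label_map).tolist())
        unknown = present - set(self.vocabulary)
        if unknown:
            raise ConfigError(f"label_map contains ids missing from vocabulary: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape  # type: ignore[return-value]

    def label_at(self, x_px: int, y_px: int) -> str:
        return self.vocabulary[int(self.label_map[y_px, x_px])]


@dataclass(frozen=True)
class DetectedBox:
    """A labeled half-open pixel rectangle [x1, x2) x [y1, y2) with confidence."""

    x1: int
    y1: int
    x2: int
    y2: int
    label: str
    confidence: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ConfigError(f"degenerate box {self}")
        if self.x1 < 0 or self.y1 < 0:
            raise ConfigError(f"box extends outside the frame: {self}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ConfigError(f"confidence outside [0,1]: {self.confidence}")

    @property
    def area(self) -> int:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    def contains(self, x_px: int, y_px: int) -> bool:
        """Edge-inclusive point-in-box test on the pixel grid."""
        return self.x1 <= x_px <= self.x2 - 1 and self.y1 <= y_px <= self.y2 - 1


@dataclass
class PerceptionResult:
    """The two perception outputs for one frame."""

    segmentation: SemanticSegmentation
    boxes: list[DetectedBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        h, w = self.segmentation.shape
        for b in self.boxes:
            if b.x2 > w or b.y2 > h:
                raise ConfigError(f"box {b} exceeds frame {w}x{h}")


@runtime_checkable
class PerceptionBackend(Protocol):
    """What the fusion pipeline needs from any perception implementation."""

    def segment(self, frame_index: int, frame: np.ndarray) -> SemanticSegmentation: ...

    def detect(self, frame_index: int, frame: np.ndarray) -> Sequence[DetectedBox]: ...


class SyntheticBackend:
    """Deterministic perception over pre-rendered synthetic scenes.

    Built from a mapping frame index -> scene specification plus an optional
    corruption model; a given (scene, corruption, seed) always yields the
    same output. See :mod:`gazefuse.synthetic` for the scene language.
    """

    def __init__(self, scenes, corruption=None, seed: int = 0) -> None:
        from . import synthetic  # local import to avoid a cycle

        self._synthetic = synthetic
        self.scenes = dict(scenes)
        self.corruption = corruption
        self.seed = seed
        self._cache: dict[int, PerceptionResult] = {}

    def _perceive(self, frame_index: int) -> PerceptionResult:
        if frame_index not in self._cache:
            if frame_index not in self.scenes:
                raise ConfigError(f"no scene registered for frame {frame_index}")
            render = self._synthetic.render_scene(self.scenes[frame_index])
            if self.corruption is None:
                result = PerceptionResult(
                    segmentation=render.segmentation, boxes=list(render.boxes)
                )
            else:
                # per-frame seed keeps frames independent yet reproducible
                result = self._synthetic.corrupt(
                    render.boxes,
                    render.segmentation,
                    self.corruption,
                    seed=(self.seed * 100003 + frame_index) % (2**31 - 1),
                )
            self._cache[frame_index] = result
        return self._cache[frame_index]

    def segment(self, frame_index: int, frame: np.ndarray | None = None) -> SemanticSegmentation:
        return self._perceive(frame_index).segmentation

    def detect(self, frame_index: int, frame: np.ndarray | None = None) -> list[DetectedBox]:
        return list(self._perceive(frame_index).boxes)


_ADAPTERS = {
    "mask2former": ("transformers", "a pretrained panoptic/semantic segmentation adapter"),
    "yolo": ("ultralytics", "a pretrained object-detection adapter"),
}


def load_adapter(name: str, **kwargs):
    """Load an optional real-model adapter by name.

    Adapters are thin shims over third-party inference packages; when the
    package (or its weights) is unavailable this raises a
    :class:`CapabilityError` naming the backend, as the contract requires.
    """
    key = name.lower()
    if key == "synthetic":
        return SyntheticBackend(**kwargs)
    if key not in _ADAPTERS:
        raise ConfigError(f"unknown backend {name!r}; known: synthetic, {', '.join(_ADAPTERS)}")
    module, desc = _ADAPTERS[key]
    try:
        __import__(module)
    except ImportError as exc:
        raise CapabilityError(
            f"backend {name!r} ({desc}) requires the optional dependency "
            f"{module!r}, which is not installed"
        ) from exc
    raise CapabilityError(
        f"backend {name!r} is an optional adapter; supply your own weights and "
        f"wrap them behind the PerceptionBackend protocol"
    )
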