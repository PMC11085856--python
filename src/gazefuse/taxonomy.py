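"""Label merging and the resolution cascade between the two perception sources.

The segmenter and the detector use different vocabularies (urban-scene
classes vs. everyday-object classes) that draw related distinctions the
analysis may not care about: road vs. sidewalk, person vs. rider, car vs.
truck, tablet vs. cell phone. A :class:`MergeMap` folds such raw classes into
broader merged classes; resolution and evaluation can then operate at either
semantic level.

When the two sources disagree on a fixation, :func:`resolve_label` applies a
four-branch cascade: (1) no detection -> keep the segmentation label, which
always exists; (2) the labels agree after merging -> keep the agreed label;
(3) exactly one label is on the user's priority list of study-critical
objects (e.g. navigation devices in a wayfinding study) -> keep that one;
(4) otherwise trust the detection only if both its confidence and its mask
coverage clear configurable floors, else fall back to the segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigError

__all__ = [
    "MergeMap",
    "DEFAULT_MERGE_MAP",
    "ResolutionConfig",
    "merge_label",
    "resolve_label",
]


class MergeMap:
    """Raw class name -> merged class name; identity for unmapped names.

    The mapping must be idempotent: merging an already-merged name returns it
    unchanged, so applying the map twice equals applying it once.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._map = dict(mapping or {})
        for raw, merged in self._map.items():
            again = self._map.get(merged, merged)
            if again != merged:
                raise ConfigError(
                    f"merge map is not idempotent: {raw!r} -> {merged!r} -> {again!r}"
                )

    def __call__(self, label: str) -> str:
        return self._map.get(label, label)

    def __eq__(self, other) -> bool:
        return isinstance(other, MergeMap) and self._map == other._map

    def as_dict(self) -> dict[str, str]:
        return dict(self._map)

    @classmethod
    def from_yaml(cls, path) -> "MergeMap":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data.get("merge_map", data))


#: The four standard merges between the two vocabularies.
DEFAULT_MERGE_MAP = MergeMap(
    {
        "sidewalk": "sidewalk/road",
        "road": "sidewalk/road",
        "person": "person/rider",
        "rider": "person/rider",
        "car": "car/truck",
        "truck": "car/truck",
        "tablet": "tablet/cell phone",
        "cell phone": "tablet/cell phone",
    }
)


def merge_label(label: str, merge_map: MergeMap) -> str:
    """Apply the merge map (identity for unmapped names)."""
    return merge_map(label)


@dataclass(frozen=True)
class ResolutionConfig:
    """Parameters of the resolution cascade.

    ``priority_list`` is ordered: when both disagreeing labels are on it, the
    earlier entry wins. Floors apply to branch (4) only.
    """

    priority_list: tuple[str, ...] = ()
    conf_floor: float = 0.5
    cov_floor: float = 0.5
    merge_map: MergeMap = field(default_factory=lambda: DEFAULT_MERGE_MAP)

    def __post_init__(self) -> None:
        if not (0.0 <= self.conf_floor <= 1.0 and 0.0 <= self.cov_floor <= 1.0):
            raise ConfigError("confidence/coverage floors must lie in [0,1]")


def resolve_label(
    mask_label: str,
    box_label: str | None,
    coverage: float | None,
    confidence: float | None,
    cfg: ResolutionConfig,
) -> tuple[str, int]:
    """Resolve the final label for one fixation; returns (label, branch).

    The branch number (1-4) identifies which cascade rule fired and is
    recorded per annotation row for auditability.
    """
    if box_label is not None and (coverage is None or confidence is None):
        raise ValueError("a box label requires both coverage and confidence")

    if box_label is None:  # (1) the segmenter always predicts; the detector may not
        return mask_label, 1

    mm = cfg.merge_map
    merged_mask, merged_box = mm(mask_label), mm(box_label)
    if merged_mask == merged_box:  # (2) agreement (possibly only after merging);
        # the raw segmentation label is kept so the output stays in the
        # source vocabularies and merging remains a separate, later step
        return mask_label, 2

    prio = [mm(p) for p in cfg.priority_list]
    mask_rank = prio.index(merged_mask) if merged_mask in prio else None
    box_rank = prio.index(merged_box) if merged_box in prio else None
    if mask_rank is not None or box_rank is not None:  # (3) priority list
        if mask_rank is not None and box_rank is not None:
            return (mask_label, 3) if mask_rank <= box_rank else (box_label, 3)
        return (mask_label, 3) if mask_rank is not None else (box_label, 3)

    # (4) disagreement off the list: trust the box only when it is both
    # confident and covers the fixated mask well
    if confidence >= cfg.conf_floor and coverage >= cfg.cov_floor:
        return box_label, 4
    return mask_label, 4
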