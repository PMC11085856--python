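"""Deterministic synthetic scenes, gaze streams and perception corruption.

The generators make the whole pipeline testable without pretrained weights or
real recordings. A scene is a stack of depth-ranked rectangles and ellipses
over a background class, rendered with a painter's algorithm: the nearest
object wins every contested pixel, so ground-truth masks never overlap while
ground-truth boxes — each object's full pre-occlusion extent — may. That is
exactly the geometry that makes mask-coverage fusion necessary: a fixation
on a partly occluded object sits inside several boxes at once.

The class vocabulary is split between the two simulated models the way an
urban-scene segmenter and an everyday-object detector differ in practice:
the segmenter knows surfaces and street furniture (road, sidewalk, building,
sky, vegetation, person, rider, car, truck, pole, traffic sign), the
detector knows countable objects (person, car, truck, bus, bicycle, cell
phone, laptop, handbag), and some classes exist on only one side — a
hand-held tablet, for instance, has no detector class at all and no
segmentation class either: its pixels inherit the class behind them, the way
a real segmenter folds a device into the person holding it.

Gaze is simulated from a plan of (target, dwell) pairs at a nominal sampling
rate, with Gaussian jitter around each target and linear saccades between
targets. Perception corruption (missed boxes, label swaps, box jitter, false
positives, mask morphology) emulates the error modes of real models. All
generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.draw import ellipse as _ellipse
from skimage.morphology import dilation as _dilation, disk, erosion as _erosion

from .backends import DetectedBox, PerceptionResult, SemanticSegmentation
from .errors import ConfigError
from .gaze_io import GazeRecording, GazeSample, VideoMeta

__all__ = [
    "SEGMENTER_VOCAB",
    "DETECTOR_VOCAB",
    "SceneObject",
    "SceneSpec",
    "SceneRender",
    "GazePlan",
    "CorruptionSpec",
    "render_scene",
    "simulate_gaze",
    "corrupt",
    "make_exp1_scene",
    "make_exp2_scene",
    "plan_on_objects",
    "scene_to_yaml",
    "scene_from_yaml",
]

#: Urban-scene classes the simulated segmenter can name.
SEGMENTER_VOCAB = (
    "road",
    "sidewalk",
    "building",
    "sky",
    "vegetation",
    "person",
    "rider",
    "car",
    "truck",
    "pole",
    "traffic sign",
)

#: Everyday-object classes the simulated detector can name.
DETECTOR_VOCAB = (
    "person",
    "car",
    "truck",
    "bus",
    "bicycle",
    "cell phone",
    "laptop",
    "handbag",
)


@dataclass(frozen=True)
class SceneObject:
    """One layered object: a rectangle or ellipse at a unique depth rank.

    ``geometry`` is (x, y, w, h) in pixels — the top-left corner and size of
    the object's axis-aligned extent (for an ellipse, of its bounding box).
    ``seg_class`` / ``det_class`` say what each model would call the object;
    either may be None when that model's vocabulary lacks the class.
    ``true_class`` is the label a human annotator would assign.
    """

    shape: str  # "rectangle" | "ellipse"
    geometry: tuple[int, int, int, int]
    depth: int  # smaller = nearer to the camera
    seg_class: str | None = None
    det_class: str | None = None
    true_class: str | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "ellipse"):
            raise ConfigError(f"unknown shape {self.shape!r}")
        x, y, w, h = self.geometry
        if w < 1 or h < 1:
            raise ConfigError(f"object extent must be >= 1 px, got {self.geometry}")
        if self.seg_class is None and self.det_class is None and self.true_class is None:
            raise ConfigError("object must carry at least one class name")
        if self.true_class is None:
            object.__setattr__(self, "true_class", self.seg_class or self.det_class)

    @property
    def box(self) -> tuple[int, int, int, int]:
        """Full pre-occlusion extent as half-open (x1, y1, x2, y2)."""
        x, y, w, h = self.geometry
        return (x, y, x + w, y + h)


@dataclass
class SceneSpec:
    """Frame size, background class, and depth-ordered objects."""

    width: int
    height: int
    background: str = "road"
    objects: list[SceneObject] = field(default_factory=list)

    def __post_init__(self) -> None:
        depths = [o.depth for o in self.objects]
        if len(depths) != len(set(depths)):
            raise ConfigError("depth ranks must be unique")
        for o in self.objects:
            x1, y1, x2, y2 = o.box
            if x1 < 0 or y1 < 0 or x2 > self.width or y2 > self.height:
                raise ConfigError(f"object {o} extends outside the {self.width}x{self.height} frame")


@dataclass
class SceneRender:
    """Everything a rendered scene yields: image, truth maps, truth boxes."""

    frame: np.ndarray  # (H, W, 3) uint8
    segmentation: SemanticSegmentation  # ground-truth class map
    boxes: list[DetectedBox]  # ground-truth detector boxes (confidence 1.0)
    instance_map: np.ndarray  # (H, W) int, -1 = background, else object index
    spec: SceneSpec

    def true_class_at(self, x_px: int, y_px: int) -> str:
        """The label a human annotator would give the visible surface here."""
        idx = int(self.instance_map[y_px, x_px])
        if idx < 0:
            return self.spec.background
        return self.spec.objects[idx].true_class  # type: ignore[return-value]


def _class_color(name: str) -> tuple[int, int, int]:
    # stable pseudo-random palette keyed by the class name
    h = np.frombuffer(name.encode(), dtype=np.uint8).astype(np.uint64)
    v = int((h * np.arange(1, len(h) + 1, dtype=np.uint64)).sum() % 2**32)
    rng = np.random.default_rng(v)
    return tuple(int(c) for c in rng.integers(40, 230, size=3))


def _object_pixels(obj: SceneObject, height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    x, y, w, h = obj.geometry
    if obj.shape == "rectangle":
        rr, cc = np.mgrid[y : y + h, x : x + w]
        return rr.ravel(), cc.ravel()
    cy, cx = y + (h - 1) / 2.0, x + (w - 1) / 2.0
    rr, cc = _ellipse(cy, cx, h / 2.0, w / 2.0, shape=(height, width))
    return rr, cc


def render_scene(spec: SceneSpec) -> SceneRender:
    """Render a scene: painter's algorithm, nearest depth wins each pixel.

    The ground-truth segmentation paints only objects with a ``seg_class``;
    pixels of unknown-to-the-segmenter objects keep the class painted behind
    them. The instance map paints every object, and each detector box (for
    objects with a ``det_class``) is the full pre-occlusion extent, so boxes
    of objects at different depths may overlap while masks never do.
    """
    h, w = spec.height, spec.width
    vocab_names = [spec.background] + [
        o.seg_class for o in spec.objects if o.seg_class is not None
    ]
    names: list[str] = []
    for n in vocab_names:  # stable de-dup
        if n not in names:
            names.append(n)
    name_to_id = {n: i for i, n in enumerate(names)}

    label_map = np.zeros((h, w), dtype=np.int32)
    instance_map = np.full((h, w), -1, dtype=np.int32)
    frame = np.zeros((h, w, 3), dtype=np.uint8)
    frame[:] = _class_color(spec.background)

    # far to near: nearer objects overwrite
    order = sorted(range(len(spec.objects)), key=lambda i: -spec.objects[i].depth)
    for idx in order:
        obj = spec.objects[idx]
        rr, cc = _object_pixels(obj, h, w)
        instance_map[rr, cc] = idx
        frame[rr, cc] = _class_color(obj.true_class)  # type: ignore[arg-type]
        if obj.seg_class is not None:
            label_map[rr, cc] = name_to_id[obj.seg_class]

    boxes = [
        DetectedBox(*o.box, label=o.det_class, confidence=1.0)
        for o in spec.objects
        if o.det_class is not None
    ]
    seg = SemanticSegmentation(label_map=label_map, vocabulary={i: n for n, i in name_to_id.items()})
    return SceneRender(frame=frame, segmentation=seg, boxes=boxes, instance_map=instance_map, spec=spec)


@dataclass
class GazePlan:
    """Ordered (target, dwell) pairs driving the gaze simulator.

    ``targets`` holds (x_norm, y_norm, duration_s) triples. Between targets
    the eye travels linearly for ``saccade_duration`` seconds. ``noise_sigma``
    is the per-axis Gaussian jitter (normalized units) during dwells.
    """

    targets: list[tuple[float, float, float]]
    rate_hz: float = 200.0
    noise_sigma: float = 0.002
    saccade_duration: float = 0.040

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be positive")
        if any(d <= 0 for _, _, d in self.targets):
            raise ConfigError("dwell durations must be positive")
        if self.saccade_duration <= 0:
            raise ConfigError("saccade_duration must be positive")

    @property
    def total_duration(self) -> float:
        dwell = sum(d for _, _, d in self.targets)
        return dwell + self.saccade_duration * max(0, len(self.targets) - 1)


def simulate_gaze(plan: GazePlan, meta: VideoMeta, seed: int = 0) -> GazeRecording:
    """Sample a gaze stream from a plan; reproducible for a given seed."""
    rng = np.random.default_rng(seed)
    dt = 1.0 / plan.rate_hz
    ts: list[float] = []
    xs: list[float] = []
    ys: list[float] = []
    t = 0.0
    for k, (tx, ty, dwell) in enumerate(plan.targets):
        n = int(round(dwell * plan.rate_hz))
        jitter = rng.normal(0.0, plan.noise_sigma, size=(n, 2)) if plan.noise_sigma > 0 else np.zeros((n, 2))
        for i in range(n):
            ts.append(t)
            xs.append(float(min(1.0, max(0.0, tx + jitter[i, 0]))))
            ys.append(float(min(1.0, max(0.0, ty + jitter[i, 1]))))
            t += dt
        if k + 1 < len(plan.targets):
            nx, ny, _ = plan.targets[k + 1]
            m = max(1, int(round(plan.saccade_duration * plan.rate_hz)))
            for i in range(m):
                frac = (i + 1) / (m + 1)
                ts.append(t)
                xs.append(tx + frac * (nx - tx))
                ys.append(ty + frac * (ny - ty))
                t += dt
    samples = [GazeSample(t=ti, x_norm=xi, y_norm=yi) for ti, xi, yi in zip(ts, xs, ys)]
    return GazeRecording(samples=samples, rate_hz=plan.rate_hz, meta=meta)


@dataclass
class CorruptionSpec:
    """Error model applied to ground-truth perception.

    Detector-side knobs: ``miss_prob`` drops each true box; ``box_swap_prob``
    relabels a box via ``box_swap_table``; ``box_jitter_px`` shifts box edges
    uniformly within the amplitude; ``false_positive_rate`` is the expected
    number of spurious boxes per frame. Segmenter-side knobs:
    ``seg_swap_prob`` relabels an entire class region via ``seg_swap_table``
    (or to a random other class when the table has no entry);
    ``morph_radius`` dilates (>0) or erodes (<0) every non-background class
    mask. All-zero knobs leave the truth untouched.
    """

    miss_prob: float = 0.0
    box_swap_prob: float = 0.0
    box_swap_table: Mapping[str, str] = field(default_factory=dict)
    box_jitter_px: int = 0
    false_positive_rate: float = 0.0
    seg_swap_prob: float = 0.0
    seg_swap_table: Mapping[str, str] = field(default_factory=dict)
    morph_radius: int = 0
    confidence_range: tuple[float, float] = (0.55, 0.95)

    def __post_init__(self) -> None:
        for p in (self.miss_prob, self.box_swap_prob, self.seg_swap_prob):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability outside [0,1]: {p}")
        if self.false_positive_rate < 0:
            raise ConfigError("false_positive_rate must be >= 0")


def corrupt(
    boxes: Sequence[DetectedBox],
    seg: SemanticSegmentation,
    spec: CorruptionSpec,
    seed: int = 0,
) -> PerceptionResult:
    """Apply the corruption model to ground truth; deterministic per seed."""
    rng = np.random.default_rng(seed)
    h, w = seg.shape
    lo, hi = spec.confidence_range

    out_boxes: list[DetectedBox] = []
    for b in boxes:
        if rng.random() < spec.miss_prob:
            continue
        label = b.label
        if spec.box_swap_prob > 0 and rng.random() < spec.box_swap_prob:
            label = spec.box_swap_table.get(
                label, str(rng.choice([c for c in DETECTOR_VOCAB if c != label]))
            )
        x1, y1, x2, y2 = b.x1, b.y1, b.x2, b.y2
        if spec.box_jitter_px > 0:
            j = spec.box_jitter_px
            x1 = int(np.clip(x1 + rng.integers(-j, j + 1), 0, w - 1))
            y1 = int(np.clip(y1 + rng.integers(-j, j + 1), 0, h - 1))
            x2 = int(np.clip(x2 + rng.integers(-j, j + 1), x1 + 1, w))
            y2 = int(np.clip(y2 + rng.integers(-j, j + 1), y1 + 1, h))
        out_boxes.append(
            DetectedBox(x1, y1, x2, y2, label=label, confidence=float(rng.uniform(lo, hi)))
        )

    n_fp = int(rng.poisson(spec.false_positive_rate)) if spec.false_positive_rate > 0 else 0
    for _ in range(n_fp):
        bw = int(rng.integers(max(2, w // 16), max(3, w // 3)))
        bh = int(rng.integers(max(2, h // 16), max(3, h // 3)))
        x1 = int(rng.integers(0, w - bw))
        y1 = int(rng.integers(0, h - bh))
        out_boxes.append(
            DetectedBox(
                x1,
                y1,
                x1 + bw,
                y1 + bh,
                label=str(rng.choice(list(DETECTOR_VOCAB))),
                confidence=float(rng.uniform(lo, hi)),
            )
        )

    label_map = seg.label_map.copy()
    vocab = dict(seg.vocabulary)
    if spec.seg_swap_prob > 0:
        name_to_id = {n: i for i, n in vocab.items()}
        present = [i for i in np.unique(seg.label_map).tolist() if i != 0]
        for cid in present:
            if rng.random() < spec.seg_swap_prob:
                name = vocab[cid]
                target = spec.seg_swap_table.get(
                    name, str(rng.choice([c for c in SEGMENTER_VOCAB if c != name]))
                )
                if target not in name_to_id:
                    new_id = max(vocab) + 1
                    vocab[new_id] = target
                    name_to_id[target] = new_id
                label_map[seg.label_map == cid] = name_to_id[target]
    if spec.morph_radius != 0:
        footprint = disk(abs(spec.morph_radius))
        op = _dilation if spec.morph_radius > 0 else _erosion
        base = label_map.copy()
        for cid in sorted(np.unique(base).tolist()):
            if cid == 0:
                continue
            mask = op(base == cid, footprint)
            if spec.morph_radius < 0:  # eroded-away pixels fall to background
                label_map[(base == cid) & ~mask] = 0
            label_map[mask] = cid

    return PerceptionResult(
        segmentation=SemanticSegmentation(label_map=label_map, vocabulary=vocab),
        boxes=out_boxes,
    )


# -------------------------------------------------------------------------
# Scene presets: a sparse low-occlusion regime and a dense cluttered one.


def make_exp1_scene(seed: int = 0, width: int = 192, height: int = 128) -> SceneSpec:
    """Sparse street scene: few objects, little occlusion, shared vocabulary."""
    rng = np.random.default_rng(seed)
    objects = [
        SceneObject("rectangle", (0, 0, width, height // 3), depth=100, seg_class="sky"),
        SceneObject(
            "rectangle",
            (int(rng.integers(0, width // 4)), height // 6, width // 3, height // 2),
            depth=50,
            seg_class="building",
        ),
        SceneObject(
            "rectangle",
            (int(rng.integers(width // 2, 3 * width // 4)), int(2 * height // 3), width // 5, height // 5),
            depth=10,
            seg_class="car",
            det_class="car",
        ),
        SceneObject(
            "ellipse",
            (int(rng.integers(width // 8, width // 3)), int(height // 2), width // 10, int(height // 2.5)),
            depth=5,
            seg_class="person",
            det_class="person",
        ),
    ]
    return SceneSpec(width=width, height=height, background="road", objects=objects)


def make_exp2_scene(seed: int = 0, width: int = 192, height: int = 128) -> SceneSpec:
    """Dense urban scene: many objects, heavy occlusion, vocabulary gaps.

    Includes detector-only objects (a phone or handbag held in front of a
    person), segmenter-only street furniture (poles, vegetation) and objects
    known to neither model under its own name (a tablet, detected as a cell
    phone and segmented as the person behind it).
    """
    rng = np.random.default_rng(seed)
    objects: list[SceneObject] = [
        SceneObject("rectangle", (0, 0, width, height // 4), depth=1000, seg_class="sky"),
        SceneObject(
            "rectangle",
            (0, height // 8, int(width * 0.45), int(height * 0.55)),
            depth=900,
            seg_class="building",
        ),
        SceneObject(
            "rectangle",
            (int(width * 0.55), height // 8, int(width * 0.4), int(height * 0.5)),
            depth=890,
            seg_class="building",
        ),
        SceneObject(
            "ellipse",
            (int(width * 0.4), int(height * 0.2), int(width * 0.18), int(height * 0.3)),
            depth=800,
            seg_class="vegetation",
        ),
    ]
    depth = 700
    # vehicles at staggered depths so their boxes overlap
    n_cars = int(rng.integers(2, 4))
    for _ in range(n_cars):
        cw = int(rng.integers(width // 6, width // 3))
        ch = int(rng.integers(height // 6, height // 4))
        cx = int(rng.integers(0, width - cw))
        cy = int(rng.integers(int(height * 0.55), height - ch))
        cls = str(rng.choice(["car", "truck"]))
        objects.append(
            SceneObject("rectangle", (cx, cy, cw, ch), depth=depth, seg_class=cls, det_class=cls)
        )
        depth -= 17
    # pedestrians, possibly in front of vehicles
    n_people = int(rng.integers(2, 4))
    person_geoms: list[tuple[int, int, int, int]] = []
    for _ in range(n_people):
        pw = int(rng.integers(width // 14, width // 8))
        ph = int(rng.integers(height // 3, height // 2))
        px = int(rng.integers(0, width - pw))
        py = int(rng.integers(int(height * 0.45), height - ph))
        person_geoms.append((px, py, pw, ph))
        objects.append(
            SceneObject("ellipse", (px, py, pw, ph), depth=depth, seg_class="person", det_class="person")
        )
        depth -= 17
    # street furniture the detector cannot name
    objects.append(
        SceneObject(
            "rectangle",
            (int(rng.integers(0, width - 4)), int(height * 0.3), 3, int(height * 0.5)),
            depth=depth,
            seg_class="pole",
        )
    )
    depth -= 17
    # hand-held devices the segmenter cannot name, in front of a person
    px, py, pw, ph = person_geoms[0]
    dw, dh = max(4, pw // 2), max(3, ph // 6)
    objects.append(
        SceneObject(
            "rectangle",
            (min(px + pw // 4, width - dw), min(py + ph // 3, height - dh), dw, dh),
            depth=depth,
            det_class="cell phone",
        )
    )
    depth -= 17
    if len(person_geoms) > 1:
        px, py, pw, ph = person_geoms[1]
        # a tablet: no detector class of its own; detected as "cell phone"
        objects.append(
            SceneObject(
                "rectangle",
                (min(px + pw // 4, width - dw), min(py + ph // 2, height - dh), dw, dh),
                depth=depth,
                det_class="cell phone",
                true_class="tablet",
            )
        )
    return SceneSpec(width=width, height=height, background="road", objects=objects)


def plan_on_objects(
    render: SceneRender,
    n_fixations: int,
    seed: int = 0,
    dwell_range: tuple[float, float] = (0.12, 0.30),
    noise_sigma: float = 0.002,
) -> tuple[GazePlan, list[str]]:
    """A gaze plan whose targets land on visible object pixels.

    Each target is a uniformly drawn visible pixel of a uniformly drawn
    object (background included occasionally via its own pixels). Returns
    the plan plus the true class of each target's surface — the manual
    'ground truth' a human annotator would produce.
    """
    rng = np.random.default_rng(seed)
    h, w = render.instance_map.shape
    targets: list[tuple[float, float, float]] = []
    truths: list[str] = []
    candidates = list(range(len(render.spec.objects)))
    for _ in range(n_fixations):
        obj_idx = int(rng.choice(candidates))
        ys, xs = np.nonzero(render.instance_map == obj_idx)
        if ys.size == 0:  # fully occluded: fall back to any visible pixel
            ys, xs = np.nonzero(render.instance_map >= -1)
        k = int(rng.integers(0, ys.size))
        x_px, y_px = int(xs[k]), int(ys[k])
        # center of the pixel keeps the normalized->pixel mapping exact
        targets.append(
            (
                (x_px + 0.5) / w,
                (y_px + 0.5) / h,
                float(rng.uniform(*dwell_range)),
            )
        )
        truths.append(render.true_class_at(x_px, y_px))
    plan = GazePlan(targets=targets, noise_sigma=noise_sigma)
    return plan, truths


# -------------------------------------------------------------------------
# YAML scene round-trip (used by the make-fixtures CLI).


def scene_to_yaml(spec: SceneSpec, path) -> None:
    import yaml

    data = {
        "width": spec.width,
        "height": spec.height,
        "background": spec.background,
        "objects": [
            {
                "shape": o.shape,
                "geometry": list(o.geometry),
                "depth": o.depth,
                "seg_class": o.seg_class,
                "det_class": o.det_class,
                "true_class": o.true_class,
            }
            for o in spec.objects
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def scene_from_yaml(path) -> SceneSpec:
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return SceneSpec(
        width=data["width"],
        height=data["height"],
        background=data.get("background", "road"),
        objects=[
            SceneObject(
                shape=o["shape"],
                geometry=tuple(o["geometry"]),
                depth=o["depth"],
                seg_class=o.get("seg_class"),
                det_class=o.get("det_class"),
                true_class=o.get("true_class"),
            )
            for o in data.get("objects", [])
        ],
    )
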