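# gazefuse

Automatic fixation annotation for mobile (head-worn) eye tracking.

Researchers who record gaze with eye-tracking glasses in the wild — urban
wayfinding studies, pedestrian navigation, shopper behavior — face a
bottleneck: every fixation must be labeled with the object the participant
looked at, and doing that by hand over egocentric video takes hours per
recording minute. `gazefuse` automates the step. It detects fixations in the
gaze stream, maps each onto its video frame, asks two complementary
perception models what is under the fixation — a dense semantic segmenter
(precise object boundaries, small vocabulary, no instances) and an object
detector (instance boxes with confidences, different vocabulary, boxes
overlap) — and fuses the two answers into a single label per fixation.

## The method

**Fixation detection.** The dispersion-threshold algorithm (IDT): a window of
consecutive samples is a fixation when its dispersion
`(max x − min x) + (max y − min y)` stays below a threshold for at least a
minimum duration (default 100 ms). Each fixation is represented by its
centroid and the video frame at its temporal midpoint.

**Mask-coverage fusion.** Segmentation masks partition the frame, so a
fixation lies in exactly one mask *M*; detection boxes may overlap, so it can
lie in several boxes. For every box *(x₁, y₁)–(x₂, y₂)* that contains both
the fixation point and at least one pixel of *M*, the mask coverage is

```
C = Σ_{(i,j) ∈ R} M_{i,j} / ((x₂ − x₁)(y₂ − y₁))
```

where *R* is the restriction of *M* to the box. The box with the greatest
*C* is selected: a tight box around the fixated object scores near 1, a
large box belonging to a closer occluder scores near 0, which is what
disambiguates objects at different depths or in close proximity (a phone
held in front of a person).

**Label resolution.** When the two models disagree, a four-branch cascade
decides: keep agreement (also agreement up to label merging, e.g.
person/rider); default to the segmentation when the detector is silent
(segmentation is total, so every fixation gets a label — no "background");
prioritize classes on a study-critical list (e.g. navigation devices);
otherwise trust the detection only if its confidence and coverage clear
configurable floors. Related classes can be merged (sidewalk/road,
person/rider, car/truck, tablet/cell phone) for analysis at a broader
semantic level.

**Evaluation.** Against manual labels, the package reports accuracy,
per-class precision/recall/F1, macro and support-weighted averages, and
row-normalized confusion matrices with zero cells left blank — the
imbalance-aware view needed when road pixels dominate but rare classes
matter most.

A fully deterministic synthetic backend (layered scenes with occlusion,
split vocabularies, seeded corruption) makes the entire pipeline testable
without pretrained weights; adapters to real segmentation/detection models
plug in behind the same two-method contract.

## Worked example

```python
from gazefuse import (IdtConfig, PipelineConfig, VideoMeta, run_pipeline,
                      SyntheticBackend)
from gazefuse.synthetic import make_exp2_scene, plan_on_objects, render_scene, simulate_gaze
from gazefuse.gaze_io import write_gaze_csv

spec = make_exp2_scene(seed=1)                       # dense urban scene
scene = render_scene(spec)
plan, truths = plan_on_objects(scene, 5, seed=2)     # 5 planted fixations
meta = VideoMeta(width=spec.width, height=spec.height, fps=30.0,
                 duration=plan.total_duration + 1.0)
write_gaze_csv(simulate_gaze(plan, meta, seed=3), "gaze.csv")

backend = SyntheticBackend({i: spec for i in range(meta.n_frames)})
cfg = PipelineConfig(gaze_path="gaze.csv", out_dir="out", meta=meta,
                     idt=IdtConfig(dispersion_threshold=0.05, unit="normalized"))
result = run_pipeline(cfg, backend)
for a in result.annotations:
    print(a.frame_index, a.mask_label, a.box_label, a.resolved_label)
```

prints one line per detected fixation, e.g.

```
2 person cell phone cell phone
8 car car car
15 vegetation None vegetation
22 person cell phone cell phone
28 person person person
```

Line 1: the segmenter called the fixated pixels *person*, but a confident,
high-coverage *cell phone* box sits exactly there — the fusion resolves to
the device the participant actually looked at. Line 3: the detector had
nothing to say about vegetation; the segmentation label is kept, so the
fixation is still annotated.

The same workflow is available from the shell:

```sh
gazefuse make-fixtures --out-dir fx --regime exp2-like --seed 1
gazefuse annotate fx/gaze.csv --scene fx/scene.yaml --out-dir out --duration 10 --dispersion 0.05
gazefuse evaluate --pred out/annotations.csv --truth manual.csv --out report.json --plot cm.png
```

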