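# Methods

## Pipeline model

`gazefuse` treats fixation annotation as four stages with explicit
contracts:

1. **Gaze ingestion** — gaze arrives as delimited text, one row per sample:
   time (s) and normalized scene-camera coordinates in [0, 1]². The internal
   convention is origin top-left, y down; exports with y up are flipped at
   load (`y_axis="up"`). Pixel conversion is
   `px = min(floor(x·W), W−1)` (floored, never rounded), which is total on
   the closed unit square. If the export already carries a device-computed
   frame index it is kept and trusted; otherwise time maps to frames as
   `floor(t·fps)` capped at the last frame.
2. **IDT fixation detection** — the classic dispersion-threshold sweep: seed
   a window spanning the duration threshold, accept and grow it while
   dispersion `(Δx + Δy)` stays within the threshold, else slide by one
   sample. Emitted fixations are disjoint, ordered, and satisfy both
   thresholds by construction.
3. **Perception** — two models per fixated frame behind one protocol: a
   semantic segmentation that partitions the frame (every pixel exactly one
   class) and an object detector returning possibly-overlapping labeled
   boxes with confidences.
4. **Fusion and resolution** — mask-coverage box selection followed by the
   four-branch label-resolution cascade (see README); the branch taken is
   recorded per row for audit.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `dispersion_threshold` | 0.02 | degrees | common device-export setting for head-worn trackers; see anomaly note below |
| `duration_threshold` | 0.100 | s | conventional minimum fixation duration |
| `fov_deg` | none | degrees | required to convert a degree threshold to normalized units (`thr/fov`, isotropic); device-specific, so no default |
| `component_mode` | `component` | — | the fixated mask is the 4-connected component under the fixation; `class` (all same-class pixels) is kept for strict literalism but lets distant same-class regions inflate coverage of unrelated boxes |
| `conf_floor`, `cov_floor` | 0.5, 0.5 | — | branch-4 gates on detector confidence and mask coverage; midpoint of both scales, configurable |
| `priority_list` | empty | ordered names | study-critical classes; when both disagreeing labels are on it, the earlier entry wins |
| `clamp_policy` | `clamp` | — | trackers emit slightly out-of-frame samples during blinks; clamping (logged) preserves sample count |

**Threshold anomaly.** The 0.02° default dispersion threshold is far below
typical IDT settings (~0.5–1°). It reproduces a configuration reported for
this class of recordings faithfully rather than silently "fixing" it; users
working in degrees should check their exporter's convention and set the
threshold and `fov_deg` accordingly. All synthetic tests use explicit
normalized thresholds, so nothing in the test suite depends on this value.

## Numerical and tie-break choices

- Coverage is counted in exact integer arithmetic (boolean pixel count over
  integer box area); only the final ratio is floating point, so the
  brute-force oracle agreement is exact, not approximate.
- Box selection ties break by higher confidence, then smaller area, then
  lowest (x₁, y₁) lexicographically — the last step guarantees full
  determinism even for identical boxes.
- Point-in-box is edge-inclusive on the pixel grid (`x₁ ≤ p ≤ x₂−1`), so
  fixations on a box border are never dropped.
- A candidate needs ≥ 1 mask pixel inside the box (C > 0); no minimum
  fraction is imposed.
- Metrics: precision/recall of never-predicted/absent classes default to 0
  (`zero_division="0"`; `"exclude"` drops undefined values from the macro
  mean); classes with zero truth support are excluded from macro and
  weighted averages. Weighted recall then equals accuracy exactly — an
  algebraic identity the tests assert to 1e−12.
- Merging is applied at resolution/evaluation time, not inside fusion, so
  the output CSV keeps the raw labels of both sources alongside the merged
  resolved label.

## The synthetic generator

The generator emulates the structure of real mobile-eye-tracking material at
desk scale: 200 Hz gaze with Gaussian dwell jitter and linear saccades;
30 fps frame timing; layered urban scenes where ground-truth boxes are full
pre-occlusion extents (so boxes overlap across depths) while ground-truth
masks are painted by a painter's algorithm (so masks never overlap); a
vocabulary split between the two models, including detector-only classes
(cell phone, handbag), segmenter-only classes (building, pole) and a class
neither model names (a tablet, detected as *cell phone*, segmented as the
surface behind it). Corruption knobs (missed boxes, label swaps on either
side, box jitter, false positives, mask dilation/erosion) emulate observed
model error modes. Everything is a pure function of (spec, seed).

Two presets ship: `exp1-like` (few objects, low occlusion) and `exp2-like`
(many objects, heavy occlusion, vocabulary gaps). The fusion-benefit
experiment runs the `exp2-like` regime at 20 scenes × 10 fixations per seed
(200 fixations), 192×128 px frames — sizes chosen so the whole experiment,
five seeds included, completes in seconds while every class appears with
non-trivial support.

What passing tests do **not** show about real data: synthetic scenes are
axis-aligned flat-colored shapes with perfect ground truth; real perception
errors are correlated with texture, lighting and motion blur, real boxes are
not axis-perfect, and gaze error grows with head motion. The fusion-benefit
result is therefore a property of the decision logic under a plausible error
model, not a measurement of any real model pairing.

## Design choices where the design was open

- **Representative point/frame per fixation:** centroid of member samples
  and the frame at the temporal midpoint (one frame per fixation). Midpoint
  avoids onset motion blur; one-frame-per-fixation matches how annotation
  effort is usually counted.
- **Connected component vs. whole class** for the fixated mask: component
  by default (see table); the mode is recorded in output metadata.
- **Priority-list ties:** when both disagreeing labels are on the priority
  list, the earlier entry wins — list order is the user's ranking.
- **Branch-2 label:** on merged agreement (e.g. mask *rider*, box *person*)
  the raw segmentation label is kept, so the output stays in the source
  vocabularies and merging remains a separate, reversible step.
- **Real-model adapters** are optional shims that raise a capability error
  naming the missing dependency; the pipeline's accuracy claims are tied to
  the decision logic, not to any particular weights, so adapters are
  deliberately replaceable and excluded from CI.

## Known limitations

- No gaze-error model around the fixation point: a fixation a few pixels
  off an object boundary is taken at face value.
- No smooth-pursuit or blink classification; IDT only.
- Segmentation is trusted to be total; a frame where segmentation fails
  entirely is logged and skipped rather than annotated as unknown.
- Video containers are decodable only where an imageio plugin exists;
  directories of numbered frames are the primary supported source.
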