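# Methods

`orbench` is a toolkit for building and scoring a multimodal operating-room
(OR) scene question-answering benchmark without access to any real OR
recordings. It has five parts: a synthetic scene simulator, a QA generation
engine for 23 scene-understanding tasks, a diversity-aware sampler, a
composite 0–1 scoring suite with bootstrap confidence intervals, and a
knowledge-distillation kernel. This note records the models, parameter
choices and numerical conventions, and what the synthetic data does and does
not establish.

## Scene simulator

Each case is a timeline of annotated timepoints in a rectangular room
(default extent 10 m × 6 m × 3 m, origin at the floor center; default image
size 640 × 480 px). Four pseudo-dataset profiles mirror the annotation
structure of the public dataset families the benchmark concept draws on:

| profile | modalities |
|---|---|
| `mvor-like` | multi-view person boxes, 3D positions, phases (3 views) |
| `4dor-like` | + scene-graph triplets, clinical roles, attributes (6 views) |
| `egosurgery-like` | single egocentric view, tool boxes, gaze fixations, phases |
| `mmor-like` | all modalities incl. robot log, sterility, monitor text, transcripts |

Mechanics and the reasoning behind them:

* **Clock.** Timepoint spacing is uniform on [5, 15] s, so timestamps are
  strictly increasing and phase durations are irregular, as in recorded
  surgeries.
* **Phases** form a contiguous ordered partition of the timeline
  (preparation → incision → drilling → sawing → implant placement →
  closing — a generic knee-replacement-style workflow; the taxonomy of real
  phase labels is not modeled, so generic tokens are used). Phase progress is
  linear within a phase, hence monotone — which the progress-estimation task
  relies on.
* **Motion.** Persons and tools random-walk with per-step displacement capped
  at 0.25 m and reflected at the walls; static equipment does not move. The
  cap gives bounded box motion between consecutive timepoints, a property
  real tracking annotations have.
* **Cameras** are overhead pinhole views (focal 260 px) placed over the room
  center and quarter points. Boxes are the projection of an entity's physical
  extent, clipped to the image; a box is dropped when nothing visible
  remains. Convention: 0-based pixel xyxy, top-left inclusive, bottom-right
  exclusive.
* **Robot workflow** is a fixed 8-step finite-state sequence (docking …
  undocking) traversed once per case with random dwell times; the final step
  has successor `end`. "Calibrated" becomes true once the calibration step
  completes.
* **Sterility.** Surgeon-side roles (head surgeon, assistant, scrub nurse)
  are sterile; each tool is independently non-sterile with probability 0.3.
  In half of the fully-annotated cases (configurable `breach_fraction`, default
  0.5) a contiguous breach interval injects a `(head_surgeon, touching,
  <non-sterile tool>)` triplet, so breach questions have both polarities.
* **Gaze** fixates the current phase tool's box center plus N(0, 4 px) noise,
  guaranteeing a resolvable ground-truth target most of the time.
* **Monitor text** is a random-walking vitals string; transcripts are a
  rolling tail (≤ 5 sentences) drawn from a small utterance bank.
* **Reproducibility.** Each case uses its own `SeedSequence(seed, source,
  case)` stream, so corpora are byte-identical under a fixed seed and cases
  are independently reproducible.

Splits are assigned per case (never per timepoint) with largest-remainder
rounding within each source; an empty split steals one case from the largest
so all three splits are nonempty. At least 3 cases per source are required.

## QA engine

Exactly 23 tasks are registered, from people counting through monitor-text
recognition. Each has one canonical question template with slot filling;
paraphrase banks are an extension point, not a default. Ground truth is a
pure function of the stored scene record, so stored answers re-derive
identically after serialization.

Gating is by modality profile: scene-graph tasks require `scene_graphs`;
robot-state and sterility tasks require the fully multimodal profile
(`scene_graphs` + `robot_log`); gaze tasks require `gaze`; geometric tasks
require the respective geometry fields. Entity-referencing questions are only
generated for classes that are unambiguous (unique) in the scene at that
timepoint. Distance questions pair all persons with each other and the head
surgeon with every other entity — enough pairs for a rich pool without a
quadratic blowup.

Numeric conventions: distances rounded to 2 decimals of a meter, times to
integer seconds, progress to integer percent, 3D points to 2 decimals. The
sorted-entities task orders classes by ascending box-center x in a designated
reference view (`view0`); left-to-right is otherwise underdetermined.
Time-until questions are only generated for future actions; past actions are
covered by "was X already performed" questions instead. Scene-graph triplets
serialize as `(subject, predicate, object)`, semicolon-separated.

## Diversity sampler

Sampling is stratified: split → source → task → weighted draw. Split
boundaries are never crossed. Source proportions default to 0.40
MM-OR-like / 0.30 EgoSurgery-like / 0.20 4D-OR-like / 0.10 MVOR-like; task
quotas within a source are uniform with the remainder spread
deterministically in task order. Within a stratum, each item's weight is
1 / (question-template count × answer-bin count), so long-tail answers are
prioritized; the weight formula is this package's concrete reading of
"inverse question and answer frequency", and the mixing weights are applied
at the source stratum level. Continuous answers are binned to define answer
frequency: scalars by fixed width (0.25 m / 10 s / 10 %), boxes and 2D points
by an 8 × 8 image grid on the box center, 3D points by 0.5 m cells.

Weighted sampling without replacement uses exponential-sort keys
(Efraimidis–Spirakis, key `u^(1/w)`), applied to the stratum sorted by
`qa_id`, making draws deterministic under a seed and independent of pool
ordering. An exhausted stratum contributes everything it has; the shortfall
is recorded in the manifest rather than silently redistributed.

Default target sizes are 1,000,000 / 10,000 / 10,000 (train/val/test), all
scale-configurable; tests and the acceptance pipeline run at reduced sizes
(100,000-pair draws for the mixing check; a 2,000/200/200 benchmark for the
end-to-end run) chosen so every stratum quota is covered by the generated
pools.

## Scoring

Every task maps to exactly one rule; all per-item scores lie in [0, 1]:

* people counting: 1.0 exact, 0.5 off by one, else 0;
* set tasks (roles, tools, entities): set IoU, with ∅ vs ∅ = 1;
* single-label and binary tasks: exact match after normalization
  (case-fold, trim punctuation, collapse whitespace);
* relative-error tasks (3D distance, progress, time-until): 1.0 when
  |pred − truth|/|truth| < 0.10, 0.5 when < 0.25, else 0 — strict
  inequalities; zero truth matches only a zero prediction;
* 2D localization: tiered box IoU, 1.0 / 0.75 / 0.5 / 0.25 at inclusive
  thresholds 0.75 / 0.5 / 0.25 / 0.125;
* scene graphs: macro F1 over the predicate classes observed in truth or
  prediction (not a fixed vocabulary), exact-triplet matches;
* sorted entities: 1 − token Levenshtein distance / max length (distance
  converted to a similarity so higher is better);
* monitor text: BLEU-1 — clipped unigram precision × brevity penalty
  `exp(min(0, 1 − r/c))`.

3D localization and gaze location have no standard printed rule; this package
reuses the relative-error tiers on Euclidean error normalized by the room
diagonal (≈ 12.04 m at defaults) and image diagonal (800 px) respectively —
a design substitute, flagged as such. Missing or unparseable predictions
score 0.0 (conservative) and are counted separately.

Aggregation is the item mean overall (micro), per task, and per source; the
per-task macro mean is also reported since the appropriate weighting is a
matter of taste. Confidence intervals are 95% percentile bootstrap over items
(1,000 resamples, seeded); intervals are clamped to bracket the point
estimate, and n < 2 degenerates to a zero-width interval with a warning.

Prediction parsing is deliberately lenient (leading yes/no token, first
number for scalars, first four numbers for boxes, comma/semicolon lists,
parenthesized triplets) because free-text systems rarely emit the canonical
form; `serialize → parse` is the identity on every canonical answer.

## Statistical baseline

Per task: modal serialized answer for categorical/set/sequence/triplet/text
tasks (ties broken lexicographically; counts are treated as categorical since
mode is the natural "most frequent answer" for them), arithmetic mean for
scalars, coordinate-wise mean for boxes and points. A uniform-random guesser
(an answer drawn uniformly from the task's training answers per question)
provides a weaker reference; on diversity-sampled synthetic benchmarks the
modal baseline consistently beats it, driven by the geometric and scalar
tasks where a mean is much better than a random draw.

## Distillation kernel

The loss is `KL(softmax(z_t/T) || softmax(z_s/T)) · T²`, averaged over batch
items (the reduction is a package choice), with KL in nats — the natural-log
reading of the summation `Σ P log(P/Q)`. `T²` keeps gradient magnitude
roughly temperature-invariant; the gradient w.r.t. student logits is
`T (Q − P) / batch`. The loss is zero exactly when the student logits equal
the teacher's up to a per-item constant (softmax shift invariance).

Students are initialized by cropping the top-left (leading rows/columns)
submatrix of each teacher weight matrix, and biases take leading entries;
cropping is idempotent at equal dims and composes. Progressive shrinking
trains a chain of students with non-increasing hidden dimensions, each
initialized from its predecessor and trained against the *original* teacher's
logits with Adam (default T = 2, lr = 0.05, batch 256) on standard-normal
synthetic inputs. The demo networks are one-hidden-layer tanh classifiers —
small enough that the kernel's identities and convergence are checkable
exactly; distilling real language models is out of scope. An optional
hard-label mixing weight exists conceptually but defaults to the pure KL
loss. Non-finite losses abort with a diagnostic rather than continuing.

## What the synthetic data does and does not show

The simulator reproduces the *annotation structure* (modalities, gating,
workflow logic, geometry conventions) of multimodal OR datasets, not their
content: there are no images, no real class-imbalance or annotation noise, no
occlusion, no inter-annotator disagreement, and scene graphs follow a small
deterministic grammar. Passing tests therefore establish that the benchmark
machinery — generation, sampling, scoring, baseline, distillation math — is
correct and reproducible, not that any model score on the synthetic benchmark
transfers to real OR data. Published headline scores of real systems depend
on the real datasets and trained models and are not reproducible here; the
per-rule worked examples, invariants and scaled-down pipeline checks are the
verifiable surface.

## Known limitations

* Overhead pinhole cameras only; no egocentric head motion model — the
  egocentric profile differs from the others only in its modality subset and
  single view.
* One question template per task; linguistic diversity must come from a
  paraphrase extension.
* The answer-bin widths that define "answer frequency" are fixed defaults;
  very differently scaled rooms or images would warrant retuning.
* `fit_baseline` treats set/sequence answers as whole answers (modal full
  answer), not per-element assemblies.
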