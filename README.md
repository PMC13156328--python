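# orbench

A toolkit for constructing and scoring multimodal **operating-room scene
question-answering benchmarks** — for surgical data science researchers who
want to evaluate scene-understanding systems (people counting, role and tool
detection, scene graphs, robot workflow state, sterility monitoring, gaze,
spatial reasoning, monitor OCR) without distributing or downloading any real
OR recordings.

The toolkit covers the whole benchmark lifecycle:

1. **Simulate** annotation-only OR scene timelines. Four pseudo-dataset
   profiles mirror the annotation structure of public OR dataset families
   (multi-view boxes + 3D positions; + scene graphs/roles/attributes;
   egocentric tool boxes + gaze; fully multimodal with robot logs, sterility,
   monitor text and transcripts). No pixels are rendered — only annotations.
2. **Generate QA pairs** for 23 tasks from fixed templates, with ground truth
   derived purely from the scene record and strict task/modality gating.
3. **Diversity-sample** a benchmark: stratified by split, source (defaults
   0.40/0.30/0.20/0.10 across the four sources) and task, weighted by
   inverse question-template and inverse answer-bin frequency
   (w ∝ 1/(n_question · n_answer-bin)), drawn without replacement via
   exponential-sort keys so results are seed-deterministic.
4. **Score** predictions with a composite 0–1 metric: per task it applies
   exact/off-by-one counting, set IoU, label matching, relative-error tiers
   (<10% → 1.0, <25% → 0.5), tiered box IoU (≥0.75/0.5/0.25/0.125 →
   1.0/0.75/0.5/0.25), macro F1 over scene-graph predicates, normalized
   token Levenshtein, and BLEU-1 — then averages per task, per source and
   overall with 95% bootstrap confidence intervals (1,000 resamples).
5. **Baseline & distill**: a most-frequent-answer statistical baseline
   (mode per task; mean for scalars/boxes/points), and a knowledge-
   distillation kernel implementing L = KL(σ(z_t/T) ‖ σ(z_s/T))·T² with
   top-left weight-crop student initialization and progressive shrinking,
   demonstrated on toy networks.

## Worked example

```python
from orbench import (SimConfig, simulate_corpus, assign_splits, generate_for_case,
                     SamplerConfig, sample_benchmark, fit_baseline,
                     predict_baseline, score_benchmark)

cfg = SimConfig(n_cases_per_source=4, timepoints_per_case=50, seed=1)
corpus = simulate_corpus(cfg)                      # 16 cases, 4 sources
splits = assign_splits([(tl.case_id, tl.source_tag) for tl in corpus],
                       (0.5, 0.25, 0.25), seed=1)
pool = []
for tl in corpus:
    for qa in generate_for_case(tl):
        qa.split = splits[tl.case_id]
        pool.append(qa)                            # ~53,000 QA pairs

bench = sample_benchmark(pool, SamplerConfig(
    target_sizes={"train": 2000, "val": 200, "test": 200}), seed=1)
model = fit_baseline(bench.splits["train"])
test = bench.splits["test"]
report = score_benchmark(test, predict_baseline(model, test), seed=1)
print(f"baseline overall: {report.overall.mean:.3f} "
      f"[{report.overall.lo:.3f}, {report.overall.hi:.3f}]")
```

prints

```
baseline overall: 0.379 [0.321, 0.441]
```

i.e. the constant most-frequent-answer predictor reaches a composite score of
0.379 on this synthetic 200-item test split, with a 95% bootstrap CI of
[0.321, 0.441] — the floor any learned model must clear. A uniform-random
guesser averages ≈ 0.30 on the same benchmark. Scoring ground truth against
itself yields exactly 1.0 on every task.

The same pipeline is available from the shell:

```bash
orbench run --seed 3 --out out/            # generate → qa → sample → baseline → score
orbench distill-demo --schedule 16,8 --steps 300 --seed 0
```

The distillation demo prints, per student, the parameter count, final loss
and argmax agreement with the teacher (e.g. a hidden-8 student reaching
0.97 agreement after 300 steps).

## Layout

```
src/orbench/
  simulate.py   scene simulator, projection, split assignment
  qa.py         23-task registry, templates, ground-truth derivation
  sampler.py    answer binning, frequency tables, stratified diversity sampling
  scoring.py    per-task rules, aggregation, bootstrap CIs
  baseline.py   most-frequent-answer baseline + random guesser
  answers.py    canonical answer values, serialization, lenient parsing
  distill.py    distillation loss, weight cropping, progressive shrinking
  io.py, cli.py JSON/JSONL persistence and the `orbench` CLI
```

See `docs/methods.md` for the full account of the simulator's assumptions,
the scoring conventions, and what synthetic-data results do and do not show.
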