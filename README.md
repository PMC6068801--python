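# stepfuse

Weak-label generation for smartphone human-activity recognition, plus the
machinery to test how classifiers trained on those weak labels behave.

The core idea: step cadence (steps/minute) and GPS speed each carry partial
information about what a person is doing.  A fuzzy heuristic turns both into
per-activity membership values — Gaussians for walking/running cadence, a
trapezoid for sedentary cadence, trapezoids for per-activity speed — and
fuses them with an accuracy-weighted average

```
P = (p_step + w_gps * p_gps) / (1 + w_gps)
```

into probability-scored weak labels over five classes (sitting, walking,
running, cycling, transportation).  Intervals whose best probability falls
below 0.5 stay unlabeled (MISSING).  Downstream, 1-second accelerometer
windows yield an 18-feature vector, weak labels are aligned with them,
classes are balanced by discarding the lowest-quality weak labels first
(keeping at most 1.3x the minimum class), and classifiers are evaluated by
fitting on weak labels and scoring against manual labels — including under
injected label noise.

Everything runs on synthetic free-living traces generated by the built-in
simulator, so no data downloads are needed.

## Layout

| Module                | Role                                                        |
|-----------------------|-------------------------------------------------------------|
| `stepfuse.types`      | activities, streams, segments, labeled rows                 |
| `stepfuse.io`         | CSV readers/writers incl. manual label-log semantics        |
| `stepfuse.simulate`   | schedule + accelerometer/step/GPS trace generator           |
| `stepfuse.labeler`    | cadence windows, merging, GPS speed, fuzzy fusion, smoothing|
| `stepfuse.features`   | 1-s/50%-overlap windows, 18-feature extraction              |
| `stepfuse.dataset`    | alignment into rows, quality-aware balancing                |
| `stepfuse.evaluate`   | 7-model suite, weak-train/true-test CV, noise experiments   |
| `stepfuse.cli`        | `stepfuse` command chaining all stages                      |

## CLI

```bash
# full pipeline: simulate -> weak-label -> extract -> build -> evaluate
stepfuse run-all --seed 1 --days 0.1 --out runs/demo

# or stage by stage
stepfuse simulate  --days 0.1 --seed 1 --out runs/demo
stepfuse weak-label --steps runs/demo/steps.csv --gps runs/demo/gps.csv --out runs/demo/weak.csv
stepfuse extract   --accel runs/demo/accel.csv --out runs/demo/features.csv
stepfuse build     --features runs/demo/features.csv --weak runs/demo/weak.csv \
                   --truth runs/demo/labels.csv --out runs/demo/dataset.csv
stepfuse evaluate  --dataset runs/demo/dataset.csv --models all --folds 10 \
                   --noise 0,0.1,0.2 --seed 1 --report runs/demo/report.json
```

All stage constants that are tool defaults rather than physical anchors
(membership spreads, trapezoid vertices, reference GPS accuracy `a0`, the
GPS gate `w_min`, threshold `theta`, PSD peak floor) live in a single YAML
config; pass `--config cfg.yaml` to any command.  `RunConfig().save(path)`
writes the defaults.

## File schemas

CSV with a header row, UTF-8, time in seconds from recording start,
half-open intervals `[start, end)`:
accelerometer `t,x,y,z` (30 Hz, units of g); steps `t`; GPS
`t,lat,lon,accuracy`; manual label log `t,tag` with `tag` an activity,
`ERROR` or `STOP`; weak labels `start,end,activity,probability`; dataset
`label,weak_label,f1..f18` (+ optional `probability,window_start`).
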