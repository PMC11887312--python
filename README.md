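# accelagree

Agreement analysis for paired wearable activity monitors, built as a tested,
reusable pipeline. Two devices are worn on one belt: an "AG"-style monitor
exporting minute-epoch vector-magnitude counts and steps, and an "OM"-style
monitor exporting minute-epoch METs plus day-epoch step totals. The package

- reads/writes the minute-epoch and day-epoch CSV dialects (`epoch_io`),
- classifies non-wear on the AG count stream with a configurable
  zero-run/spike-tolerance heuristic (default 90/2/30) and propagates the
  mask to the OM stream (`wear_time`),
- merges the streams, classifies MVPA minutes (METs ≥ 3.0; vector-magnitude
  counts ≥ 2690), aggregates to participant-days with asymmetric wear
  handling — daily steps retain non-wear minutes, MVPA excludes them — and
  applies the valid-day filter (wear ≥ 600 min, 100 ≤ steps < 50 000 on both
  devices) (`daily_builder`),
- fits Gaussian random-intercept models by profiled REML to produce
  multilevel Bland-Altman limits of agreement
  (mean ± 1.96·√(σ²_between + σ²_within)) and a proportional-bias slope of
  the difference on the pairwise mean with a Wald z test (`agreement`),
- renders Bland-Altman figures and orchestrates everything behind a CLI
  (`report_cli`),
- and simulates paired streams with known ground truth at two fidelity
  levels — direct daily differences, and full minute-level Markov-state
  streams with injected non-wear bouts and device biases — for end-to-end
  validation (`synthetic_data`). The stream dynamics are invented for
  testing purposes and are not a model of real free-living behaviour.

## CLI

```bash
# generate a synthetic reference dataset (3 input CSVs + ground-truth CSV)
accelagree simulate --out data/ --seed 1

# full pipeline from a config file; writes daily.csv, agreement.json,
# ba_steps.png, ba_mvpa.png and run.log into --out
accelagree all --config run.yaml --out results/run1 --seed 1

# stages individually
accelagree agree  --daily results/run1/daily.csv --out results/agree.json
accelagree report --daily results/run1/daily.csv --out results/figs
```

A config file covers every run option; provide either `inputs` (paths) or
`simulate` (generator settings), never both:

```yaml
simulate:            # or: inputs: {ag_minutes: ..., om_minutes: ..., om_daily: ...}
  n_subjects: 129
  days_per_subject: 7
  seed: 1
wear:      {window_minutes: 90, spike_tolerance_minutes: 2, flank_minutes: 30}
cutpoints: {om_mvpa_mets: 3.0, ag_mvpa_cpm: 2690}
valid_day: {min_wear_minutes: 600, min_steps: 100, max_steps: 50000}
loa_multiplier: 1.96
```

All thresholds in effect are echoed into `agreement.json`; stage-by-stage
observation counts (read → merged → worn → valid) go to stderr and
`run.log`. Re-running an identical config reproduces byte-identical CSV and
JSON outputs.

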