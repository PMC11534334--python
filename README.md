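# tmreeg — sleep-EEG analysis of targeted memory reactivation

Targeted memory reactivation (TMR) re-presents learning-associated sound
cues during non-REM sleep to bias memory consolidation. Testing whether it
worked requires a chain of analyses: detect cue-locked slow waves (SW,
0.5–3 Hz) and fast sleep spindles (12–16 Hz), classify spindles as nested
in the SW up-state (envelope peak 0.3–0.8 s after a trough), compare
up-state spindle-band power between cueing conditions with cluster-based
permutation statistics, and score the behavioral discrimination task with
signal detection theory,

    d' = z(hits) − z(false alarms),    c = −0.5 (z(false alarms) + z(hits)),

with rates of 0 and 1 replaced by 0.5/n and (n−0.5)/n. `tmreeg` implements
this pipeline as a library for sleep/memory researchers, together with a
synthetic-data generator that injects slow waves, coupled spindle bursts
and two-condition behavior with known ground truth, so every stage is
testable without access to raw recordings.

The package provides:

* `io_core` — EDF/BrainVision recordings, event/stage tables (TSV), epochs;
* `synthetic` — 1/f background EEG, 8±2 s cue trains, SW/spindle injection,
  reward-categorization behavior (160 words × 3 presentations = 480
  encoding trials; 160-trial memory tests);
* `preprocessing` — mastoid re-referencing, zero-phase band-passes,
  epoching, peak-to-peak artifact rejection;
* `timefrequency` — 7-cycle Morlet power (µV²), absolute-change baseline;
* `sw` / `spindles` — the event detectors with top-30% amplitude selection
  and per-subject 1.25/0.75 SD envelope thresholds;
* `coupling` — up-state coupling and SW-trough-locked spectra;
* `cluster_stats` — cluster-based permutation tests over
  channel × frequency × time, t-tests with Cohen's d, Pearson correlations;
* `behavior` — SDT scoring and overnight changes;
* `pipeline` / `cli` — one-config orchestration (`tmreeg run-all`) and
  stage-wise subcommands (`simulate`, `preprocess`, `tfr`, `detect-sw`,
  `detect-spindles`, `couple`, `behavior`, `stats`).

## Worked example

The numbered scripts under `analysis/` run the study on simulated data and
write their tables under `results/`. The group-level step:

```bash
python analysis/05_group_statistics.py --seed 1
```

simulates two cueing groups of 8 subjects (30 cues each) whose coupled
spindles differ in amplitude (easy/high-PP cued: 14 µV; difficult/low-PP
cued: 8 µV), detects events, computes SW-locked spectra and tests the
up-state contrast. It prints:

```
         n_sw_top  n_spindles  n_coupled  upstate_power
group
high_pp     83.50       26.25      16.25           8.53
low_pp      82.12       15.00       5.88           3.54

up-state power, high vs low: t(14) = 6.64, p = 1.1e-05, Cohen's d = 3.32
cluster test (500 permutations): 1 clusters, 1 significant
  cluster sum(t) = 3076.0, p = 0.0020, channels = ['C3', 'C4', ...]

mean overnight d' change (cued condition, by group):
group
high_pp    0.133
low_pp    -0.055
```

Reading it: both groups yield the same slow-wave counts (the SW response to
cues is condition-independent), but the group with the larger injected
coupled-spindle amplitude shows more detected spindles, more up-state
coupling, and ~2.4× the baseline-corrected 11–14 Hz up-state power; the
cluster-based permutation test flags that difference (p = 0.002), and the
simulated behavior shows an overnight d′ gain only when the easy condition
was cued. Steps 01–04 run the same machinery for a single subject
(simulation, SDT learning curves and overnight changes, detector outputs
and cue-locked densities, coupling and up-state power).

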