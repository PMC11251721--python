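# placenav

Simulation and trajectory analytics for a body-fixed VR place-preference
navigation task on a circular arena.

A synthetic-agent simulator generates behavioral sessions in four regimes
(novice, expert, dMUS, iMUS — the latter two modeling dorsal/intermediate
hippocampal inactivation) plus an object-guided probe task, and the
analysis pipeline computes every per-trial measure used to characterize
the behavior — departing direction (DD), perimeter-crossing direction
(PCD), deviation angles, perimeter-crossing counts, travel distance /
excess distance / latency / speed, first body-turn, scene-rotation traces
— together with the session-level workflow (training criteria, PRE/POST
learning windows, PBS-session merging, condition contrasts) and the
directional statistics behind it (mean resultant vectors, permutation
Kuiper two-sample test, Watson–Williams test with a 0.45 mean-vector
applicability gate, Wilcoxon signed-rank, repeated-measures ANOVA with
Greenhouse–Geisser correction and Bonferroni post hocs).

## Layout

| module | contents |
| --- | --- |
| `placenav.environment` | arena geometry, reward zones, angle conventions (clockwise-from-east) |
| `placenav.agents` | condition-parameterized trajectory simulators |
| `placenav.metrics` | per-trial measures (DD, PCD, crossings, distances, turns) |
| `placenav.circstats` | circular + within-subject statistics |
| `placenav.analysis` | session summaries, criteria, PRE/POST, PBS merge, condition contrasts |
| `placenav.io` / `placenav.cli` | trajectory CSV schema, JSON config, command line |

## CLI

```sh
placenav simulate --seed 1 --out traj.csv --conditions expert,dMUS,iMUS --subjects 8 --trials 40
placenav metrics  --in traj.csv --out metrics.csv
placenav compare  --in traj.csv --out report.json
placenav learning --in day_series.csv --out learning.json
placenav probe    --in probe_traj.csv --out probe.json
placenav report   --in traj.csv --out report_dir/
```

All commands honor `--config` (a JSON run configuration with arena
overrides, per-condition agent parameters and analysis options) and are
deterministic given `--seed`.

## Conventions

Angles are degrees measured clockwise from East (N = 270, NE = 315,
S = 90), so the high-value zone sits at 180 and the low-value zone at 0.
Lengths are meters, times seconds, speeds cm/s in reports. Trajectories
are CSV (one row per 60 Hz sample) with a `# placenav-trajectory-csv`
version stamp; configs and statistical reports are JSON.
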