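# File formats

All interadapt artifacts are plain text.

## Trial logs (`trials.csv`)

Tidy CSV, one row per sample:

| column | unit | meaning |
|---|---|---|
| subject_id | – | agent/subject identifier |
| trial_index | – | 1-based ordinal across the session |
| phase | – | `baseline` or `adaptation` |
| t | s | sample time from trial start (nominal 1/125 s spacing) |
| hand_x, hand_y | cm | hand position (start at origin, y forward) |
| cursor_x, cursor_y | cm | cursor position (hand lagged by the active delay) |
| target_x | cm | target position along the line y = reach distance |
| target_speed | cm/s | absolute target speed for the trial |
| direction | – | +1 left-to-right, −1 right-to-left |

A JSON sidecar (`session.json`) stores the `TaskConfig` and the list of
`AgentParams` used to generate the log.

## Metrics table (`metrics.csv`)

One row per trial: `subject_id, trial_index, phase, onset_t, crossing_t,
crossing_x, T, Mv, Ma, tv, TE, crossing_speed, valid`.  Times in seconds,
speeds cm/s, angles degrees; TE positive when the hand leads.

## Fits table (`fits.csv`)

One row per subject: two-state slope `a` (ms/trial), asymptote `b` (ms),
`sse` (ms²), exponential `tau` (trials), `b_e` (ms), `converged`, the
z-scores `z_a`, `z_b` and the Adaptation Score.  The packaged reference
table (`interadapt fixtures`) uses the `subject, a, b, score` subset of this
schema.

## Report (`report.json`)

Nested JSON with the exclusion report, per-subject summaries, the group
split, F-tests, sequential-effect slopes, per-subject ccf profiles with CIs,
ccf–score correlations, and the LASSO tables.  Floats are rounded to 10
decimals so reruns of the same configuration are byte-identical.

## Pipeline configuration (`config.yaml`)

YAML mirror of `PipelineConfig` with sections `task`, `filter`, the cohort
spec (`n_subjects`, `gain_range` or explicit `agents`), the seed, exclusion
thresholds, and analysis settings (bootstrap counts, AR max order, λs).
Round-trips through serialization unchanged; its SHA-256 hash is recorded in
`manifest.json`.
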