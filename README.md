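# fetalmotion

Automated detection of gross fetal movement in overnight two-channel
(abdomen / thigh) accelerometer recordings.

The pipeline band-limits both channels (0.5–2.5 Hz, notches at 1.0 Hz for
the maternal heartbeat and 0.3 Hz for respiration on the fetal channel),
reduces them to 50-ms rectified integrals, and detects bursts whose
integral exceeds 200 % of the surrounding ±3-s mean plus a fixed minimum
(15 fetal / 20 maternal device units). Detected fetal events are then
screened against maternal artifacts: maternal body movement and periodic
limb movement on the reference channel, maternal wake/restroom periods
(excised from analysis time), and fetal hiccup trains (> 15 short signals
per minute, excluded from counts but not from analysis time). Quality
control uses a 0–40-s inter-event-interval histogram with respiration
(3–5-s columns) and hiccup (2-s column) suspect flags. Summary statistics
include 10-s epoch labels, PABAK/kappa agreement between two labelings,
movements per hour, and a one-way repeated-measures ANOVA with Scheffé
post-hoc contrasts across gestational-week sessions.

Since no real recordings ship with the package, `fetalmotion.synthetic`
generates ground-truth-labeled recordings containing every signal class
(fetal bursts, heartbeat, REM-irregular respiration, maternal movements,
PLM trains, hiccup bouts, wake/restroom periods) via a fixed-seed
scenario library.

## Command-line use

```sh
# make a synthetic night and analyse it end to end
fetalmotion simulate --scenario quiet_night --out rec.csv --truth truth.csv
fetalmotion run --in rec.csv --out results/

# individual stages
fetalmotion filter --in rec.csv --out filtered.csv
fetalmotion detect --in rec.csv --events events.csv --integrals integrals.csv
fetalmotion reject --events events.csv --total-s 3600 --out final.csv --mask mask.csv
fetalmotion qc --events final.csv --out hist.csv --flags flags.json
fetalmotion summarize --events final.csv --mask mask.csv --meta rec.json --out summary.json
fetalmotion agree --a labels_a.csv --b labels_b.csv
fetalmotion anova --table sessions.csv
```

`fetalmotion run` (and `qc`) exit with status 3 when a respiration or
hiccup suspect flag is raised, signalling that detection should be re-run
with adjusted thresholds. All outputs are deterministic: identical input
and configuration produce byte-identical files.

Recordings are plain CSV (`fm,mm` or `time_s,fm,mm` columns) with a JSON
sidecar of the same stem holding `sampling_rate`, `subject_id` and
`gestational_week`. The full pipeline configuration round-trips through a
single JSON file (`fetalmotion run --config cfg.json`); unknown keys are
rejected.

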