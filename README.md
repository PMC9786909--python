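# stepsense

Open-source wrist-accelerometer step counting with concurrent-validity
tooling. The package implements a peak-detection step-count algorithm for raw
tri-axial wrist accelerometry (two shipped threshold presets: the original
`verisense1` and the bias-optimized `verisense2`), derives 5-s epoch cadence
and MVPA steps (≥100 steps/min), collapses them to paired daily summaries,
and quantifies agreement against a reference device with Bland–Altman
statistics, proportional-bias regression, MAPE, and exhaustive parameter-grid
tuning. A deterministic gait/artefact simulator provides recordings with
known ground-truth steps so the whole pipeline is testable offline.

## Layout

| module               | role |
|----------------------|------|
| `stepsense.signal_io` | raw CSV I/O, linear resampling, vector magnitude, ENMO epochs |
| `stepsense.step_core` | candidate peak detection + magnitude/periodicity/similarity/continuity filters; `count_steps` and the loop-based `naive_count_steps` test oracle |
| `stepsense.metrics`   | epoch aggregation, cadence/MVPA classification, daily summaries, day pairing |
| `stepsense.agreement` | Bland–Altman bias/LoA/CI, proportional bias, MAPE, percent bias, grid tuning |
| `stepsense.simulator` | synthetic gait bouts, arm-movement artefacts, 24-h day scenarios, imperfect reference device |
| `stepsense.app`       | `stepsense` CLI and the end-to-end pipeline with a run manifest |

The algorithm operates at 15 Hz: the magnitude signal is linearly resampled
to that rate before peak detection, so all "sample"-denominated thresholds
(periodicity windows, continuity windows) are in 15 Hz samples. Presets are
also shipped as JSON under `src/stepsense/presets/`.

## CLI

```bash
# simulate a day with ground truth and a reference daily log
stepsense simulate --scenario scenario.json --seed 7 --out-dir sim/

# count steps in a raw CSV, write 5-s epochs
stepsense count --input sim/raw.csv --params verisense2 --out epochs.csv

# collapse epochs to daily summaries
stepsense daily --epochs epochs.csv --out daily.csv

# Bland–Altman agreement from a paired daily CSV
stepsense agree --pairs paired.csv --metric total --out agreement.json

# grid-search thresholds against labelled recordings (<name>.csv + <name>.ref)
stepsense tune --grid grid.json --data data/ --out tuning.csv

# full pipeline with manifest
stepsense run --input sim/raw.csv --reference sim/reference_daily.csv \
    --agree --out-dir out/
```

Raw CSV dialect: optional `# sample_rate_hz=...` metadata lines, header
`timestamp_iso8601,accel_x_g,accel_y_g,accel_z_g`, accelerations in g at six
decimal places.

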