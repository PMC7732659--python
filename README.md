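# paskit

A toolkit for experience-sampling studies that use the **sensor-based
Physical Analogue Scale (PAS)**: a wrist-worn device whose button press
records the forearm's elevation — flat (0°) to fully upright (90°) — as a
continuous rating read from the accelerometer. Because answering takes one
arm movement and a press, the PAS can capture frequent and fleeting
everyday events (the motivating application is *social media ostracism*:
a sent message seen but left unanswered) with minimal interruption burden.

`paskit` is aimed at researchers running or re-analysing such studies. It
covers the full measurement pipeline:

- **angle** — the accelerometer transform
  `angle = arctan(|y| / √(x² + z²)) · 180/π` and its inverse for
  simulation; linear mapping onto response scales.
- **protocol** — device-log parsing, grouping presses into bursts,
  category coding (1 press = ignored by a single recipient, 2 = ignored by
  a group, 3 = time-based baseline), test-response and over-press
  filtering with full accounting, within-burst consistency ICC.
- **scheduler** — reproducible randomized prompt times within daily
  windows.
- **compliance** — prompt/response matching, daily compliance rates, and
  attrition correction ("non-response before end of study").
- **psychometrics** — Cronbach's α, PAS–VAS concordance, SPSS-style curve
  estimation (linear/log/quadratic/exponential R²), and accuracy reports
  against a target angle.
- **multilevel** — the random-intercept, random-slope two-level model of
  occasion-level ratings

  `y_ti = β₀₀ + β₁₀·single_ti + β₂₀·group_ti + r₀ᵢ + r₁ᵢ·single_ti + r₂ᵢ·group_ti + e_ti`

  fit by REML, with null-model ICC, Ω² explained variance, the
  group-vs-single Wald contrast, cross-level moderation scans, and a
  Monte-Carlo power analysis for the design.
- **simulator** — complete synthetic studies (latent offendedness, event
  streams, prompts, sensor encoding, non-response, attrition) written as
  device logs, plus parameter-recovery experiments that push every
  replicate through the full parse → classify → fit pipeline.

## Worked example

Simulate the two-week ostracism design (53 persons, two daily baseline
prompts, Poisson event arrivals) from the shipped preset, parse its device
log, and fit the multilevel model:

```bash
paskit simulate --preset ostracism --seed 7 --out-dir sim
# simulated 4510 presses from 53 devices

paskit parse --log sim/device_log.csv --angle-mode extended --out bursts.csv
# 2040 assessments kept (159 test, 47 over-press removed)
```

The parse step removed each device's three familiarization bursts (159 =
53 × 3) and the ~2% of responses followed by more than three presses, and
categorised the rest. Reshape the burst table into occasions (person id,
angle as the offendedness outcome, category dummies) and analyse:

```bash
paskit analyze --occasions occasions.csv --out table1.csv
# ICC=0.095 Omega^2=0.172 contrast=5.03 (p=0.0093)
```

`table1.csv` holds the fixed-effect table of this replicate:

| term | estimate | SE | t |
|---|---|---|---|
| Intercept | 13.84 | 0.68 | 20.4 |
| single_chat | 6.77 | 1.01 | 6.7 |
| group_chat | 11.81 | 1.77 | 6.7 |

Participants in this synthetic study feel 13.8° offended at baseline, 6.8°
more after being ignored by a single recipient and 11.8° more after being
ignored by a group — recovering the preset's generative values (13.5 / 7.0
/ 11.5) within sampling error. The ICC says ~9% of rating variance is
between persons; Ω² = 0.17 is the share of within-person variance the event
dummies explain; the significant contrast (5.03°, p = 0.009) is the extra
sting of group over single-recipient ostracism. Compliance accounting:

```bash
paskit compliance --schedule sim/prompts.csv --bursts bursts.csv --out daily.csv
# overall compliance 0.573; daily rates in daily.csv
```

Every artifact-writing command drops a JSON run manifest (seeds, config
hash, paths) next to its outputs; identical seeds reproduce outputs
byte-for-byte.

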