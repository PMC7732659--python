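# Methods

This note documents the models and procedures implemented in `paskit`, the
choices made where the design was genuinely open, and what the synthetic
studies do and do not establish.

## The Physical Analogue Scale measurement model

A wrist-worn device records, at each button press, the accelerometer
triplet (x, y, z) with `y` along the forearm. Under a still arm the triplet
is the gravity vector, and the forearm's elevation is

    angle = arctan(|y| / sqrt(x^2 + z^2)) * 180 / pi  in [0, 90].

Because the transform is a ratio it is unit-free (g or m/s^2) and invariant
to sign flips of any axis and to common positive rescaling. A zero triplet
(free fall, sensor dropout) carries no orientation and is rejected rather
than silently recorded as 0 degrees. No gravity/linear-acceleration
separation, gyroscope fusion, or per-device calibration is attempted — the
protocol has participants hold the pose while pressing.

Ratings map linearly onto response scales (0 deg -> scale minimum,
90 deg -> maximum); the PAS-vs-VAS validation battery (`psychometrics`)
found no material nonlinearity, so no curvature correction is offered.

### Extended (sign-preserving) encoding

The device transform folds every orientation into [0, 90]. The simulator,
however, must represent latent ratings that a *linear* model produces, and
those exceed the physical range whenever the baseline mean is within about
two residual SDs of 0. For that purpose `angle_to_accel(..., extended=True)`
keeps the signs of `y` and of the horizontal component, and the matching
decoder uses `atan2(y, sign(x)*hypot(x, z))`. On [0, 90] the two conventions
agree exactly; outside, the extended form represents "virtual" angles so the
log round trip is lossless. Real device logs should always be parsed in
`device` mode (the default); `extended` mode exists for simulated studies
with scale clipping off.

## Device protocol

Logs are comma-separated text (`device_id,timestamp,x,y,z,press_index`),
ISO 8601 timestamps with offsets, one row per press. Presses chain into a
burst while consecutive gaps are at most `gap_seconds` (default 2 s — the
firmware stores press counts but no grouping rule, so this is a toolkit
decision; it is configurable). The press count encodes the category:
1 = ignored by a single recipient, 2 = ignored by a group, 3 = time-based
baseline. Bursts with more than three presses are discarded as accidental
over-presses, and bursts before a device's familiarization cutoff (default:
10 minutes after its first record; configurable per device) are test
responses. The analysis angle of a burst is the angle at its *first* press —
the participant establishes the pose, then presses; later presses are count
signals. All per-press angles are retained, and `press_consistency_icc`
summarises within-burst agreement as a one-way random-effects ICC with the
usual average-group-size correction for unbalanced burst sizes.

## Prompt scheduling

Time-based prompts are drawn uniformly and independently within each
configured daily window (e.g. 10:00-16:00 and 16:00-22:00), one per window
per day, with no cross-window spacing constraint — the simplest scheme
consistent with "random signal times". Each device draws from its own RNG
stream derived from (study seed, CRC32 of device id), so schedules are
reproducible and adding a device never perturbs the others.

## Compliance

A prompt counts as answered if a baseline (triple-press) burst from the
same device occurs within `response_window_minutes` after it (default 60
minutes; the matching rule is a toolkit decision and is echoed in the
output metadata). Each burst answers at most one prompt, the earliest
unmatched one. The attrition-corrected rate removes, per device, all
prompts after its last recorded burst of *any* category, separating
"stopped answering prompts" from "stopped participating"; corrected daily
rates are therefore never below raw rates, and days whose denominators
empty out are flagged rather than reported as 0/0.

## Multilevel model

Occasions (level 1) nest in persons (level 2):

    y_ti = b00 + b10 single_ti + b20 group_ti + r0i + r1i single_ti + r2i group_ti + e_ti

Estimation is REML via statsmodels' `MixedLM` (ML togglable). The three
random effects are independent (diagonal covariance) by default — reported
results in this design tradition give SDs only — with a full covariance
available by flag. The intercept-only null model yields
ICC = tau0 / (tau0 + sigma^2); explained variance is
Omega^2 = 1 - sigma^2_full / sigma^2_null, floored at zero with a warning.
The group-vs-single contrast b20 - b10 is a Wald test on the fixed-effect
covariance. Person-level covariates enter the intercept equation after
grand-mean centering, except sex, which keeps its 1 = female / 2 = male
coding. Standardized coefficients, when requested, z-score the outcome and
all non-dummy predictors before refitting (dummies stay raw); this
convention is recorded in the fit's notes.

Outcomes are analysed on the raw degree scale without truncation handling:
the linear mixed model ignores the bounded scale, which is why the
simulator's clipping mode must be off for recovery experiments (below).
Numerical strategy: statsmodels' default optimizer (with its internal
retries) first, then BFGS, CG and Powell; if none reports convergence the
best candidate by restricted likelihood is returned with `converged=False`,
and an error is raised only when every optimizer fails outright. Boundary
estimates (a variance component at 0) are reported as SD 0.

`moderation_scan` fits one model per person-level covariate, adding its
cross-level interaction with both event dummies, and tabulates the
interaction estimates and p-values. A constant moderator is an error.

### Power analysis

`power_min_n` finds the smallest N whose Monte-Carlo rejection rate reaches
the target. The generative model for the simulation is a reduced two-level
design on the residual-SD = 1 scale: random intercept variance fixed by the
assumed ICC (default 0.089), a person-specific event slope (SD 0.3 by
default), events Bernoulli(0.5) per occasion, and a standardized mean event
effect (0.3 ~ medium). The test statistic is the one-sample t over person
mean event-minus-baseline differences — exact at level alpha under this
model and fast enough to vectorise thousands of replicates — so the power
estimate is conservative relative to a full mixed-model Wald test. The
search doubles N, then bisects, with a deterministic RNG stream per
candidate N. All assumptions are echoed in the output.

## Synthetic studies

`GenerativeConfig` defaults are the two-week field design: 53 persons,
14 days, two daily prompts (10-16 h, 16-22 h) answered with probability
0.594 (the observed mean compliance), and Poisson ostracism events at 1.34
single-recipient and 0.34 group events per person-day (the rates implied by
991 and 250 events over 53 x 14 person-days). Fixed effects are
13.5 / 7.0 / 11.5 degrees and random-effect SDs 3.29 / 5.43 / 8.88. Event
times are uniform over waking hours (08-22 h, a toolkit choice; arrival
structure in the field is unknown and Poisson is a declared
simplification). Each device writes a familiarization sequence (1-, 2-,
3-press test bursts) before the field phase, and 2.1% of response bursts
gain extra presses beyond three, exercising both filter rules. Attrition is
off by default and available as a per-day geometric dropout hazard plus a
final-day non-response spike for realism demonstrations of the compliance
curve. Person covariates are independent standard normals (sex ~ 81%
female, age ~ N(26.5, 9.56) clipped to 18-57); no level-2 effects are
injected by default, with a hook via the config for moderation power
studies.

### Residual-SD calibration

The configuration pins the null-model ICC (default 8.9%) rather than the
residual SD. The intercept-only model applied to event-sampling data sees
more than tau0 on both levels: with per-occasion category probabilities
p_s, p_g implied by the event rates and prompt compliance,

    between = tau0 + tau1 p_s^2 + tau2 p_g^2
    mix     = (b10^2 + tau1) p_s + (b20^2 + tau2) p_g - (b10 p_s + b20 p_g)^2

and the residual variance solving ICC = between / (tau0 + mix + sigma^2) is

    sigma^2 = between / ICC - tau0 - mix.

For the default configuration this gives sigma ~ 12.46 degrees. The naive
ratio tau0/(tau0 + sigma^2) = 0.089 would instead give sigma ~ 10.53 and an
observed null ICC near 11% — the event mix cannot be ignored. The same
moment algebra yields the population Omega^2 (~0.174 at the defaults).
An infeasible target (event mix alone pushing the ICC below target) raises
a configuration error.

### Clipping and recovery

With `clip_to_scale` on, occasion values are truncated to [0, 90] before
encoding — realistic, but it biases a linear refit: at the default
parameters (baseline mean 13.5, residual SD ~12.5) the lower bound cuts a
noticeable tail and the recovered intercept is biased upward. Recovery
experiments therefore run with clipping off and the extended encoding, and
the truncation bias is asserted directionally in the tests rather than
ignored. First-press measurement noise (`angle_noise_sd`) defaults to 0 —
the residual e_ti already absorbs measurement error in the fitted model, so
adding sensor noise on top would double-count it; later presses within a
burst get a small re-read jitter (SD 1 degree) so within-burst consistency
is high but not degenerate.

`recovery_experiment` regenerates a study per replicate, pushes its log
through parse -> group -> classify, fits the null and saturated models, and
reports per-parameter mean, SD, bias and Monte-Carlo SE. At 100 replicates
of the default design the fixed effects, the ICC, the contrast and the
random-effect SDs are recovered within Monte-Carlo error (the tests assert
3 MC SEs); the problem size (100 replicates, ~2,100 occasions each) keeps a
full run around five minutes on one core.

### What the simulator does not emulate

Real event streams may be bursty rather than Poisson; compliance in the
field drifts over days rather than staying at a constant response
probability; device orientation noise is angle-scale Gaussian here, not a
physical IMU model; and questionnaire item-level responses are not
simulated (only scale scores). Passing recovery tests therefore shows the
*pipeline* is consistent — parsing, classification, filtering and
estimation introduce no bias — not that the generative model captures every
feature of field data.

## Known limitations

- The bounded outcome is modelled linearly, as in the design this toolkit
  follows; censored or beta-type models are a possible extension.
- REML convergence is optimizer-reported; small designs with many level-2
  covariates may return best-effort fits flagged `converged=False`.
- The familiarization cutoff is a heuristic (first 10 minutes per device)
  unless explicit per-device cutoffs are supplied.
- Residual autocorrelation within days is not modelled.
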