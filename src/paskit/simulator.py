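"""Synthetic PAS studies: the generative model run forward.

Generates complete studies — persons with latent offendedness parameters,
social-media-ostracism events, randomized time-based prompts, sensor
encoding, non-response and attrition — and writes device logs in the
:mod:`paskit.protocol` dialect, so the whole parse -> classify -> fit
pipeline can be exercised and scored against known ground truth.

Generative model (defaults = the 2-week ostracism study design):

* 53 persons observed for 14 days; per person draw r0i, r1i, r2i from
  independent zero-mean normals (SDs 3.29 / 5.43 / 8.88 degrees).
* Each day, single-recipient and group events arrive as Poisson counts
  (rates 1.34 and 0.34 per person-day — the rates implied by 991 and 250
  events over 53 x 14 person-days), at uniform times over waking hours.
* Two time-based prompts per day (10:00-16:00, 16:00-22:00) are answered
  with probability 0.594 each (the observed mean compliance).
* Occasion value: y = b00 + r0i + (b10 + r1i)*single + (b20 + r2i)*group + e,
  e ~ N(0, residual_sd).  With ``residual_sd=None`` the residual SD is
  calibrated in closed form so the null-model ICC of the generated data is
  ``target_icc`` (default 8.9%) — see :func:`residual_sd_for_icc`.
* The value is written to the log as an accelerometer triplet.  With
  ``clip_to_scale`` ON, values are clipped to the physical 0-90 range first
  (realistic, but truncation biases a linear refit).  With it OFF the
  sign-preserving extended encoding keeps out-of-range values intact so the
  linear model is exactly recoverable; parameter-recovery runs use OFF.
* Presses: 1 / 2 / 3 per category, ~0.4 s apart; later presses re-read the
  angle with a small jitter (within-burst consistency stays high, as on the
  real device).  A small fraction of bursts (2.1%) gains extra presses
  beyond three and is later discarded by the filter, and each device starts
  with a familiarization sequence (1-, 2-, 3-press test bursts) that the
  filter removes as test responses.

Identical master seed => byte-identical device log.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta, timezone

import numpy as np
import pandas as pd

from . import multilevel, protocol, scheduler
from .angle import angle_to_accel
from .errors import ConfigError, InputError
from .protocol import RawRecord, link_key

__all__ = [
    "GenerativeConfig",
    "SyntheticStudy",
    "residual_sd_for_icc",
    "generative_omega_squared",
    "simulate_study",
    "run_pipeline",
    "recovery_experiment",
    "RecoveryReport",
]


@dataclass
class GenerativeConfig:
    """All knobs of the study generator (defaults = the ostracism study)."""

    n_persons: int = 53
    n_days: int = 14
    beta_baseline: float = 13.5     # b00, degrees
    beta_single: float = 7.0        # b10
    beta_group: float = 11.5        # b20
    sd_intercept: float = 3.29      # SD of r0i
    sd_single_slope: float = 5.43   # SD of r1i
    sd_group_slope: float = 8.88    # SD of r2i
    residual_sd: float | None = None  # None -> calibrate to target_icc
    target_icc: float = 0.089
    rate_single: float = 1.34       # events / person-day
    rate_group: float = 0.34
    prompt_windows: tuple[str, ...] = ("10:00-16:00", "16:00-22:00")
    response_prob: float = 0.594    # per prompt
    attrition_hazard: float = 0.0   # per-day probability of going silent
    final_day_nonresponse: float = 0.0  # extra non-response on the last day
    angle_noise_sd: float = 0.0     # measurement noise on the first press
    press_jitter_sd: float = 1.0    # re-read jitter on presses 2..k
    clip_to_scale: bool = False
    include_familiarization: bool = True
    overpress_rate: float = 0.021   # fraction of bursts gaining >3 presses
    event_hours: tuple[float, float] = (8.0, 22.0)
    start_date: date = date(2019, 3, 4)
    tz_hours: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        sds = (
            self.sd_intercept, self.sd_single_slope, self.sd_group_slope,
            self.angle_noise_sd, self.press_jitter_sd,
        )
        if any(s < 0 for s in sds) or (self.residual_sd is not None and self.residual_sd < 0):
            raise ConfigError("standard deviations must be >= 0")
        if self.rate_single < 0 or self.rate_group < 0:
            raise ConfigError("event rates must be >= 0")
        for p in (self.response_prob, self.attrition_hazard, self.final_day_nonresponse):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.n_persons < 1 or self.n_days < 1:
            raise ConfigError("n_persons and n_days must be >= 1")
        if not 0 < self.target_icc < 1:
            raise ConfigError("target_icc must be in (0, 1)")
        if not 0 <= self.event_hours[0] < self.event_hours[1] <= 24:
            raise ConfigError("event_hours must satisfy 0 <= start < end <= 24")
        scheduler.validate_windows([scheduler.parse_window(w) for w in self.prompt_windows])

    @property
    def tz(self) -> timezone:
        return timezone(timedelta(hours=self.tz_hours))

    def windows(self) -> list[scheduler.PromptWindow]:
        return [scheduler.parse_window(w) for w in self.prompt_windows]

    def occasion_mix(self) -> tuple[float, float]:
        """Expected per-occasion probabilities (p_single, p_group)."""
        lam_s, lam_g = self.rate_single, self.rate_group
        lam_b = len(self.prompt_windows) * self.response_prob
        total = lam_s + lam_g + lam_b
        if total == 0:
            raise ConfigError("no occasions would ever be generated")
        return lam_s / total, lam_g / total

    def resolved_residual_sd(self) -> float:
        if self.residual_sd is not None:
            return self.residual_sd
        return residual_sd_for_icc(self)


def residual_sd_for_icc(cfg: GenerativeConfig, target_icc: float | None = None) -> float:
    """Residual SD that makes the null-model ICC of generated data hit target.

    The intercept-only model sees more than the intercept variance on both
    levels: with per-occasion event probabilities p_s, p_g (from the event
    rates and prompt compliance), person means absorb

        between = tau0 + tau1*p_s^2 + tau2*p_g^2

    while the occasion-to-occasion scatter picks up the event effects and
    slope heterogeneity,

        mix = (b10^2 + tau1)*p_s + (b20^2 + tau2)*p_g
              - (b10*p_s + b20*p_g)^2.

    Setting ICC = between / (tau0 + mix + sigma^2) and solving:

        sigma^2 = between / ICC - tau0 - mix.

    Raises :class:`~paskit.errors.ConfigError` if the target is infeasible
    (the event mix alone already pushes the ICC below target).
    """
    icc = cfg.target_icc if target_icc is None else target_icc
    p_s, p_g = cfg.occasion_mix()
    tau0 = cfg.sd_intercept**2
    tau1 = cfg.sd_single_slope**2
    tau2 = cfg.sd_group_slope**2
    b10, b20 = cfg.beta_single, cfg.beta_group
    between = tau0 + tau1 * p_s**2 + tau2 * p_g**2
    mix = (b10**2 + tau1) * p_s + (b20**2 + tau2) * p_g - (b10 * p_s + b20 * p_g) ** 2
    sigma2 = between / icc - tau0 - mix
    if sigma2 <= 0:
        raise ConfigError(
            f"target ICC {icc} infeasible: implied residual variance {sigma2:.3f} <= 0"
        )
    return float(np.sqrt(sigma2))


def generative_omega_squared(cfg: GenerativeConfig) -> float:
    """Omega^2 implied by the generative parameters (population value).

    The null model's residual variance is the within-person variance:
    sigma^2 plus the event mix, minus the share of slope heterogeneity that
    lands between persons (tau1*p_s^2 + tau2*p_g^2, which the null model's
    person intercepts absorb).  The saturated model's residual is sigma^2
    alone, so Omega^2 = 1 - sigma^2 / within_null.
    """
    p_s, p_g = cfg.occasion_mix()
    tau1 = cfg.sd_single_slope**2
    tau2 = cfg.sd_group_slope**2
    b10, b20 = cfg.beta_single, cfg.beta_group
    mix = (b10**2 + tau1) * p_s + (b20**2 + tau2) * p_g - (b10 * p_s + b20 * p_g) ** 2
    sigma2 = cfg.resolved_residual_sd() ** 2
    within_null = sigma2 + mix - (tau1 * p_s**2 + tau2 * p_g**2)
    return float(1.0 - sigma2 / within_null)


@dataclass
class SyntheticStudy:
    """A generated study with lossless ground truth for recovery scoring."""

    config: GenerativeConfig
    residual_sd: float
    records: list[RawRecord]
    schedules: list[scheduler.PromptSchedule]
    persons: pd.DataFrame        # device_id, link_key, r0/r1/r2, covariates, dropout_day
    occasions: pd.DataFrame      # device_id, timestamp, category, true_value, angle_written

    def log_text(self) -> str:
        return protocol.log_to_text(self.records)

    def write(self, log_path, prompt_path=None, persons_path=None) -> None:
        protocol.write_log(self.records, log_path)
        if prompt_path is not None:
            pd.concat([s.to_frame() for s in self.schedules]).to_csv(prompt_path, index=False)
        if persons_path is not None:
            self.persons.to_csv(persons_path, index=False)


def _device_id(i: int) -> str:
    """MAC-like device id whose first four hex digits are unique per person."""
    hi, lo = 0x40 | ((i >> 8) & 0x3F), i & 0xFF
    return f"{hi:02X}:{lo:02X}:3E:2A:91:7C"


_MIN_BURST_SEPARATION_S = 10.0
_PRESS_GAP_RANGE_S = (0.25, 0.60)


def _ms(dt: datetime) -> datetime:
    """Quantize to whole milliseconds, the log dialect's resolution."""
    return dt.replace(microsecond=(dt.microsecond // 1000) * 1000)

_COVARIATE_SPECS = [
    # (name, sampler description) — independent person-level traits; sex and
    # age follow the study sample's composition, the scales are standardised.
    "self_esteem", "extraversion", "neuroticism", "openness",
    "agreeableness", "conscientiousness", "text_msg_dependency",
    "narcissism", "cse_og",
]


def simulate_study(cfg: GenerativeConfig) -> SyntheticStudy:
    """Run the generative model forward into a device log plus ground truth."""
    cfg.validate()
    residual_sd = cfg.resolved_residual_sd()
    master = np.random.SeedSequence([int(cfg.seed)])
    rng = np.random.default_rng(master)
    windows = cfg.windows()
    tz = cfg.tz
    extended = not cfg.clip_to_scale

    persons_rows = []
    occasion_rows = []
    records: list[RawRecord] = []
    schedules: list[scheduler.PromptSchedule] = []

    for i in range(cfg.n_persons):
        dev = _device_id(i)
        # per-person stream so person sets are stable under n_persons changes
        prng = np.random.default_rng(
            np.random.SeedSequence(protocol.device_stream_seed(cfg.seed, dev) + [7])
        )
        r0 = prng.normal(0.0, cfg.sd_intercept)
        r1 = prng.normal(0.0, cfg.sd_single_slope)
        r2 = prng.normal(0.0, cfg.sd_group_slope)
        sex = 1 if prng.random() < 0.81 else 2
        age = int(np.clip(round(prng.normal(26.5, 9.56)), 18, 57))
        covs = {name: float(prng.standard_normal()) for name in _COVARIATE_SPECS}
        if cfg.attrition_hazard > 0:
            dropout_day = int(min(cfg.n_days, 1 + prng.geometric(cfg.attrition_hazard)))
        else:
            dropout_day = cfg.n_days
        persons_rows.append(
            {
                "device_id": dev, "person_id": dev, "link_key": link_key(dev),
                "sex": sex, "age": age, **covs,
                "r0": r0, "r1": r1, "r2": r2, "dropout_day": dropout_day,
            }
        )

        sched = scheduler.make_schedule(
            windows, cfg.start_date, cfg.n_days, cfg.seed, device_id=dev, tz=tz
        )
        schedules.append(sched)

        # familiarization: 1-, 2-, 3-press test bursts before the field phase
        occasions: list[tuple[datetime, str, int]] = []  # (time, category, presses)
        if cfg.include_familiarization:
            t0 = datetime.combine(
                cfg.start_date, time(7, 15), tzinfo=tz
            ) + timedelta(seconds=float(prng.uniform(0, 600)))
            for k in (1, 2, 3):
                occasions.append((_ms(t0 + timedelta(seconds=30 * (k - 1))), "FAMILIARIZATION", k))

        for d in range(1, cfg.n_days + 1):
            if d > dropout_day:
                break
            day = cfg.start_date + timedelta(days=d - 1)
            n_s = prng.poisson(cfg.rate_single)
            n_g = prng.poisson(cfg.rate_group)
            for cat, n in (("SINGLE_CHAT", n_s), ("GROUP_CHAT", n_g)):
                presses = 1 if cat == "SINGLE_CHAT" else 2
                for _ in range(n):
                    hour = prng.uniform(*cfg.event_hours)
                    t = datetime.combine(day, time(0, 0), tzinfo=tz) + timedelta(hours=float(hour))
                    occasions.append((_ms(t), cat, presses))
            p_resp = cfg.response_prob
            if d == cfg.n_days and cfg.final_day_nonresponse > 0:
                p_resp *= 1.0 - cfg.final_day_nonresponse
            for p in sched.prompts:
                if p.day != day:
                    continue
                if prng.random() < p_resp:
                    delay = prng.uniform(30.0, 900.0)  # answer within the hour
                    occasions.append((_ms(p.instant + timedelta(seconds=float(delay))), "BASELINE", 3))

        # chronological order; enforce separation so burst grouping is exact
        occasions.sort(key=lambda o: o[0])
        sep = timedelta(seconds=_MIN_BURST_SEPARATION_S)
        for j in range(1, len(occasions)):
            prev_t = occasions[j - 1][0]
            if occasions[j][0] - prev_t < sep:
                occasions[j] = (prev_t + sep, occasions[j][1], occasions[j][2])

        for t, cat, presses in occasions:
            if cat == "FAMILIARIZATION":
                value = float(prng.uniform(0, 90))
                single = group = 0
            else:
                single = int(cat == "SINGLE_CHAT")
                group = int(cat == "GROUP_CHAT")
                value = (
                    cfg.beta_baseline + r0
                    + (cfg.beta_single + r1) * single
                    + (cfg.beta_group + r2) * group
                    + prng.normal(0.0, residual_sd)
                )
                if cfg.clip_to_scale:
                    value = float(np.clip(value, 0.0, 90.0))
            total_presses = presses
            overpressed = False
            if cat != "FAMILIARIZATION" and cfg.overpress_rate > 0:
                if prng.random() < cfg.overpress_rate:
                    total_presses = presses + int(prng.integers(max(1, 4 - presses), 5))
                    overpressed = True
            first_angle = value
            if cfg.angle_noise_sd > 0:
                first_angle = first_angle + prng.normal(0.0, cfg.angle_noise_sd)
            if cfg.clip_to_scale:
                first_angle = float(np.clip(first_angle, 0.0, 90.0))
            press_t = t
            for k in range(1, total_presses + 1):
                ang = first_angle if k == 1 else first_angle + prng.normal(0.0, cfg.press_jitter_sd)
                if not extended:
                    ang = float(np.clip(ang, 0.0, 90.0))
                x, y, z = angle_to_accel(ang, 0.0, prng, extended=extended)
                records.append(RawRecord(dev, press_t, x, y, z, k))
                if k < total_presses:
                    press_t = _ms(
                        press_t + timedelta(seconds=float(prng.uniform(*_PRESS_GAP_RANGE_S)))
                    )
            if cat != "FAMILIARIZATION":
                occasion_rows.append(
                    {
                        "device_id": dev,
                        "timestamp": t,
                        "category": cat,
                        "true_value": value,
                        "angle_written": first_angle,
                        "presses": total_presses,
                        "overpressed": overpressed,
                        "single_chat": single,
                        "group_chat": group,
                    }
                )

    records.sort(key=lambda r: (r.device_id, r.timestamp, r.press_index))
    return SyntheticStudy(
        config=cfg,
        residual_sd=residual_sd,
        records=records,
        schedules=schedules,
        persons=pd.DataFrame(persons_rows),
        occasions=pd.DataFrame(occasion_rows),
    )


def run_pipeline(study: SyntheticStudy, *, gap_seconds: float = protocol.DEFAULT_BURST_GAP_S):
    """parse -> group -> classify the study's own log; returns (bursts, report).

    The log text round-trips through :func:`paskit.protocol.parse_log`
    exactly as a real device upload would; the angle decoder follows the
    study's clip mode.
    """
    mode = "device" if study.config.clip_to_scale else "extended"
    recs = protocol.parse_log(io.StringIO(study.log_text()))
    bursts = protocol.group_bursts(recs, gap_seconds, angle_mode=mode)
    # without familiarization bursts there is no test window to cut away
    cutoff = None if study.config.include_familiarization else {}
    return protocol.classify_and_filter(bursts, test_cutoff=cutoff)


@dataclass
class RecoveryReport:
    """Per-replicate estimates plus a bias summary for a recovery run."""

    estimates: pd.DataFrame
    truth: dict[str, float]
    n_replicates: int
    n_failed: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, true_val in self.truth.items():
            est = self.estimates[name].dropna()
            mean = est.mean()
            sd = est.std(ddof=1)
            mc_se = sd / np.sqrt(len(est))
            rows.append(
                {
                    "parameter": name,
                    "truth": true_val,
                    "mean": mean,
                    "sd": sd,
                    "bias": mean - true_val,
                    "mc_se": mc_se,
                    "n": len(est),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


def recovery_experiment(
    cfg: GenerativeConfig,
    n_replicates: int,
    seed: int | None = None,
    *,
    seeds: list[int] | None = None,
) -> RecoveryReport:
    """Simulate -> parse -> classify -> fit, repeatedly; score the estimates.

    Each replicate regenerates a full study (fresh seed), pushes its log
    through the protocol pipeline, and fits both the null and the saturated
    random-slope model.  Fit failures are counted and reported, not fatal.
    ``seeds`` overrides the per-replicate seed list; otherwise replicate k
    uses ``seed + k`` (``seed`` defaults to ``cfg.seed``).
    """
    if n_replicates < 2 and seeds is None:
        raise InputError("n_replicates must be >= 2")
    if seeds is None:
        base = cfg.seed if seed is None else int(seed)
        seeds = [base + k for k in range(n_replicates)]
    rows = []
    n_failed = 0
    for s in seeds:
        rep_cfg = replace(cfg, seed=int(s))
        study = simulate_study(rep_cfg)
        kept, _ = run_pipeline(study)
        occ = multilevel.occasions_from_bursts(kept)
        row = {"seed": int(s)}
        try:
            null = multilevel.fit_null(occ)
            full = multilevel.fit_saturated(occ)
            con = multilevel.contrast_group_vs_single(full)
            row.update(
                beta_baseline=full.fixed.loc["Intercept", "estimate"],
                beta_single=full.fixed.loc["single_chat", "estimate"],
                beta_group=full.fixed.loc["group_chat", "estimate"],
                sd_intercept=full.re_sd.get("intercept", np.nan),
                sd_single_slope=full.re_sd.get("single_chat", np.nan),
                sd_group_slope=full.re_sd.get("group_chat", np.nan),
                residual_sd=np.sqrt(full.resid_var),
                icc=null.icc,
                omega_squared=multilevel.omega_squared(full, null),
                contrast=con.estimate,
                converged=full.converged and null.converged,
            )
        except Exception:
            n_failed += 1
            row["converged"] = False
        rows.append(row)
    truth = {
        "beta_baseline": cfg.beta_baseline,
        "beta_single": cfg.beta_single,
        "beta_group": cfg.beta_group,
        "sd_intercept": cfg.sd_intercept,
        "sd_single_slope": cfg.sd_single_slope,
        "sd_group_slope": cfg.sd_group_slope,
        "residual_sd": cfg.resolved_residual_sd(),
        "icc": cfg.target_icc,
        "omega_squared": generative_omega_squared(cfg),
        "contrast": cfg.beta_group - cfg.beta_single,
    }
    est = pd.DataFrame(rows)
    for name in truth:
        if name not in est.columns:
            est[name] = np.nan
    return RecoveryReport(
        estimates=est, truth=truth, n_replicates=len(seeds), n_failed=n_failed
    )
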