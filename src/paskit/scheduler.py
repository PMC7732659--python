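"""Randomized time-based prompt schedules.

Signal-contingent experience sampling issues a vibration prompt at a random
instant inside each configured daily window (e.g. once between 10:00 and
16:00 and again between 16:00 and 22:00, for 14 days).  Draws are uniform
within the window and independent across windows and days — the simplest
scheme consistent with "random signal time points"; no minimum spacing is
enforced across adjacent windows.

Reproducibility: each device gets its own RNG stream derived from the study
seed and the device id, so adding a device never perturbs the schedules of
the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta, timezone, tzinfo
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .protocol import device_stream_seed

__all__ = [
    "PromptWindow",
    "Prompt",
    "PromptSchedule",
    "parse_window",
    "validate_windows",
    "make_schedule",
]


@dataclass(frozen=True, order=True)
class PromptWindow:
    """A daily time-of-day window ``[start, end)`` for one prompt."""

    start: time
    end: time

    def __post_init__(self):
        if self.start >= self.end:
            raise ConfigError(f"window start {self.start} must precede end {self.end}")

    @property
    def seconds(self) -> float:
        return (
            datetime.combine(date.min, self.end) - datetime.combine(date.min, self.start)
        ).total_seconds()

    def __str__(self) -> str:
        return f"{self.start:%H:%M}-{self.end:%H:%M}"


def parse_window(text: str) -> PromptWindow:
    """Parse a ``"HH:MM-HH:MM"`` window string."""
    try:
        start_s, end_s = text.strip().split("-")
        return PromptWindow(time.fromisoformat(start_s), time.fromisoformat(end_s))
    except ValueError as exc:
        raise ConfigError(f"cannot parse window {text!r}: {exc}") from exc


def validate_windows(windows: Sequence[PromptWindow]) -> list[PromptWindow]:
    """Sort windows and reject overlap within a day."""
    if not windows:
        raise ConfigError("at least one prompt window is required")
    ws = sorted(windows)
    for a, b in zip(ws, ws[1:]):
        if b.start < a.end:
            raise ConfigError(f"windows {a} and {b} overlap")
    return ws


class Prompt(NamedTuple):
    day: date
    window_index: int
    instant: datetime


@dataclass
class PromptSchedule:
    """All prompts for one device over the study period."""

    device_id: str
    prompts: list[Prompt]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "device_id": self.device_id,
                "day": [p.day for p in self.prompts],
                "window_index": [p.window_index for p in self.prompts],
                "prompt_instant": [p.instant for p in self.prompts],
            }
        )


def make_schedule(
    windows: Sequence[PromptWindow],
    start_date: date,
    n_days: int,
    rng_seed: int,
    *,
    device_id: str = "",
    tz: tzinfo = timezone(timedelta(hours=1)),
) -> PromptSchedule:
    """Draw one uniform prompt instant per window per study day.

    ``rng_seed`` is the study-level seed; the actual stream is derived from
    it together with ``device_id`` (see :func:`paskit.protocol.device_stream_seed`).
    Identical inputs yield an identical schedule.
    """
    if n_days < 1:
        raise ConfigError("n_days must be >= 1")
    ws = validate_windows(windows)
    rng = np.random.default_rng(np.random.SeedSequence(device_stream_seed(rng_seed, device_id)))
    prompts: list[Prompt] = []
    for d in range(n_days):
        day = start_date + timedelta(days=d)
        for wi, w in enumerate(ws):
            offset = rng.uniform(0.0, w.seconds)
            instant = datetime.combine(day, w.start, tzinfo=tz) + timedelta(seconds=offset)
            prompts.append(Prompt(day, wi, instant))
    return PromptSchedule(device_id=device_id, prompts=prompts)
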