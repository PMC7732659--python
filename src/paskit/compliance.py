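"""Prompt-response matching and compliance accounting.

Compliance is the fraction of time-based prompts that received a baseline
(triple-press) response within a matching window after the vibration signal.
A second, attrition-corrected rate excludes prompts issued after a device's
last recorded activity of *any* category: participants who stop pressing
altogether (typically assuming the study has ended) no longer contribute to
the denominator, which separates "stopped responding to prompts" from
"left the study".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError, LinkageError
from .protocol import Category, ResponseBurst
from .scheduler import PromptSchedule

__all__ = [
    "ComplianceTable",
    "match_responses",
    "attrition_correct",
    "ignored_message_rate",
]

DEFAULT_RESPONSE_WINDOW_MIN = 60.0


@dataclass
class ComplianceTable:
    """Prompt-level matching results plus daily compliance rates.

    ``per_prompt`` has one row per (device, prompt): day index (1-based),
    instant, answered flag, and whether the prompt precedes the device's
    last activity ("active").  ``daily`` pools devices within study day:
    raw rate = answered / issued; corrected rate uses only active prompts
    (NaN where a day has no active prompts left).
    """

    per_prompt: pd.DataFrame
    daily: pd.DataFrame
    response_window_minutes: float
    metadata: dict = field(default_factory=dict)

    @property
    def overall_rate(self) -> float:
        return float(self.per_prompt["answered"].mean())


def _daily_rates(per_prompt: pd.DataFrame) -> pd.DataFrame:
    g = per_prompt.groupby("day_index")
    issued = g.size()
    answered = g["answered"].sum()
    active = per_prompt[per_prompt["active"]].groupby("day_index")
    issued_active = active.size().reindex(issued.index, fill_value=0)
    answered_active = active["answered"].sum().reindex(issued.index, fill_value=0)
    daily = pd.DataFrame(
        {
            "prompts_issued": issued,
            "prompts_answered": answered,
            "raw_rate": answered / issued,
            "prompts_active": issued_active,
            "corrected_rate": np.where(
                issued_active > 0, answered_active / issued_active.replace(0, np.nan), np.nan
            ),
        }
    )
    daily.index.name = "day_index"
    return daily.reset_index()


def match_responses(
    schedules: Iterable[PromptSchedule] | PromptSchedule,
    bursts: list[ResponseBurst],
    response_window_minutes: float = DEFAULT_RESPONSE_WINDOW_MIN,
) -> ComplianceTable:
    """Match baseline bursts to prompts and tabulate compliance.

    A prompt counts as answered when at least one baseline burst from the
    same device falls in ``[prompt, prompt + window]``; each burst answers at
    most one prompt (the earliest still-unmatched one).  Bursts of any
    category count as "activity" for the attrition correction.

    Raises :class:`~paskit.errors.LinkageError` if a baseline burst's device
    has no schedule.
    """
    if isinstance(schedules, PromptSchedule):
        schedules = [schedules]
    schedules = list(schedules)
    if response_window_minutes <= 0:
        raise InputError("response_window_minutes must be > 0")
    window = timedelta(minutes=response_window_minutes)

    sched_devices = {s.device_id for s in schedules}
    by_device_baseline: dict[str, list[ResponseBurst]] = {}
    last_activity: dict[str, datetime] = {}
    for b in bursts:
        prev = last_activity.get(b.device_id)
        if prev is None or b.timestamp > prev:
            last_activity[b.device_id] = b.timestamp
        if b.category is Category.BASELINE:
            if b.device_id not in sched_devices:
                raise LinkageError(
                    f"baseline burst from device {b.device_id!r} has no prompt schedule"
                )
            by_device_baseline.setdefault(b.device_id, []).append(b)

    rows = []
    for sched in schedules:
        dev_bursts = sorted(by_device_baseline.get(sched.device_id, []), key=lambda b: b.timestamp)
        used = [False] * len(dev_bursts)
        day0 = min((p.day for p in sched.prompts), default=None)
        last = last_activity.get(sched.device_id)
        for p in sorted(sched.prompts, key=lambda p: p.instant):
            answered = False
            matched_time = None
            for i, b in enumerate(dev_bursts):
                if used[i] or b.timestamp < p.instant:
                    continue
                if b.timestamp > p.instant + window:
                    break
                used[i] = True
                answered = True
                matched_time = b.timestamp
                break
            rows.append(
                {
                    "device_id": sched.device_id,
                    "day_index": (p.day - day0).days + 1,
                    "prompt_instant": p.instant,
                    "answered": answered,
                    "matched_time": matched_time,
                    "active": last is not None and p.instant <= last,
                }
            )
    per_prompt = pd.DataFrame(rows)
    if per_prompt.empty:
        raise InputError("no prompts in any schedule")
    return ComplianceTable(
        per_prompt=per_prompt,
        daily=_daily_rates(per_prompt),
        response_window_minutes=response_window_minutes,
        metadata={"response_window_minutes": response_window_minutes},
    )


def attrition_correct(table: ComplianceTable) -> ComplianceTable:
    """Return a table whose per-device denominators stop at last activity.

    Prompts issued after a device's last recorded burst (any category) are
    dropped from that device's rows entirely, so daily corrected rates are
    computed over still-active devices only.  The per-day corrected rate is
    always >= the raw rate of the original table (only unanswered prompts
    can be dropped); days with no remaining prompts get NaN, flagged in
    ``metadata['empty_days']`` rather than reported as 0/0.
    """
    pp = table.per_prompt[table.per_prompt["active"]].copy()
    daily = _daily_rates(table.per_prompt)
    all_days = set(table.per_prompt["day_index"])
    kept_days = set(pp["day_index"]) if not pp.empty else set()
    return ComplianceTable(
        per_prompt=pp,
        daily=daily,
        response_window_minutes=table.response_window_minutes,
        metadata={
            **table.metadata,
            "attrition_corrected": True,
            "empty_days": sorted(all_days - kept_days),
        },
    )


def ignored_message_rate(n_ignored: int, n_sent: int) -> float:
    """Percentage of sent messages that were ignored (ostracism prevalence).

    E.g. 1,241 recorded ostracism events against an estimated 25,144 sent
    messages gives ~4.9% — roughly one message in twenty.
    """
    if n_sent <= 0:
        raise InputError("n_sent must be positive")
    if n_ignored < 0:
        raise InputError("n_ignored must be non-negative")
    return 100.0 * n_ignored / n_sent
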