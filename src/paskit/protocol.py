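"""Wearable log parsing, burst grouping, classification and filtering.

Log dialect
-----------
Comma-separated text with header ``device_id,timestamp,x,y,z,press_index``:
one row per button press, ISO 8601 timestamps with UTC offset, the device
identified by its MAC address.  ``press_index`` is the 1-based ordinal of the
press within its burst as counted by the firmware.

A *burst* is a run of rapid consecutive presses on one device; the press
count encodes the response category: one press = message ignored by a single
recipient, two = ignored by a group, three = time-based baseline prompt.
Bursts recorded before a device's familiarization cutoff are test responses,
and bursts of more than three presses are discarded as accidental
over-presses; both removals are accounted for in a :class:`FilterReport`.

The angle analysed for a burst is the angle at its *first* press — the
participant sets the arm position and then presses; later presses are count
signals.  All per-press angles are retained so within-burst consistency can
be checked (:func:`press_consistency_icc`).
"""

from __future__ import annotations

import csv
import io
import os
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .angle import accel_to_angle
from .errors import FormatError, InputError, UndefinedStatisticError

__all__ = [
    "LOG_COLUMNS",
    "Category",
    "RawRecord",
    "ResponseBurst",
    "FilterReport",
    "parse_log",
    "write_log",
    "group_bursts",
    "classify_and_filter",
    "press_consistency_icc",
    "bursts_to_frame",
    "link_key",
    "device_stream_seed",
]

LOG_COLUMNS = ("device_id", "timestamp", "x", "y", "z", "press_index")

#: Default inter-press gap (seconds) that still chains presses into one burst.
DEFAULT_BURST_GAP_S = 2.0

#: Default familiarization window after a device's first record (minutes).
DEFAULT_FAMILIARIZATION_MIN = 10.0


class Category(str, Enum):
    SINGLE_CHAT = "SINGLE_CHAT"
    GROUP_CHAT = "GROUP_CHAT"
    BASELINE = "BASELINE"
    DISCARDED = "DISCARDED"
    TEST = "TEST"


#: press count -> analysis category (>=4 handled separately as DISCARDED)
PRESS_CODING = {1: Category.SINGLE_CHAT, 2: Category.GROUP_CHAT, 3: Category.BASELINE}


@dataclass(frozen=True)
class RawRecord:
    """One button press as stored by the wearable."""

    device_id: str
    timestamp: datetime
    x: float
    y: float
    z: float
    press_index: int


@dataclass(frozen=True)
class ResponseBurst:
    """A grouped run of presses; one assessment."""

    device_id: str
    timestamp: datetime          # first press
    press_count: int
    angles: tuple[float, ...]    # one per press, degrees
    category: Category | None = None
    press_indices: tuple[int, ...] = field(default=(), compare=False)

    @property
    def angle(self) -> float:
        """The analysis angle: the angle at the first press."""
        return self.angles[0]


@dataclass(frozen=True)
class FilterReport:
    """Accounting of the classification/filtering step.

    Satisfies ``n_final == n_total - n_test_removed - n_over3_removed`` and
    ``n_final == sum(counts.values())`` by construction.
    """

    n_total: int
    n_test_removed: int
    n_over3_removed: int
    n_final: int
    counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_test_removed": self.n_test_removed,
            "n_over3_removed": self.n_over3_removed,
            "n_final": self.n_final,
            "counts": dict(self.counts),
        }


def link_key(device_id: str) -> str:
    """First four hex digits of a MAC address, the anonymous questionnaire
    linkage key participants copy from the wearable's case."""
    digits = [c for c in device_id.upper() if c in "0123456789ABCDEF"]
    if len(digits) < 4:
        raise InputError(f"device id {device_id!r} has fewer than four hex digits")
    return "".join(digits[:4])


def device_stream_seed(study_seed: int, device_id: str) -> list[int]:
    """Seed material for a per-device RNG stream.

    Derived from the study seed and a CRC of the device id, so adding or
    removing devices never perturbs other devices' random draws.
    """
    return [int(study_seed), zlib.crc32(device_id.encode("utf-8"))]


# ---------------------------------------------------------------------------
# log I/O
# ---------------------------------------------------------------------------

def parse_log(path_or_buffer) -> list[RawRecord]:
    """Read a device log, validating every line.

    Accepts a filesystem path or a text file-like object.  Records are
    returned sorted by ``(device_id, timestamp, press_index)``.  All
    malformed lines are collected and reported together in a
    :class:`~paskit.errors.FormatError` carrying their 1-based line numbers.
    """
    if hasattr(path_or_buffer, "read"):
        return _parse_stream(path_or_buffer)
    if not os.path.exists(path_or_buffer):
        raise FormatError(f"log file not found: {path_or_buffer}")
    with open(path_or_buffer, newline="", encoding="utf-8") as fh:
        return _parse_stream(fh)


def _parse_stream(fh) -> list[RawRecord]:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        return []
    header = [h.strip() for h in header]
    if header != list(LOG_COLUMNS):
        raise FormatError(
            f"unexpected header {header!r}; expected {','.join(LOG_COLUMNS)}",
            lines=[1],
        )
    records: list[RawRecord] = []
    bad: list[tuple[int, str]] = []
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        try:
            records.append(_parse_row(row))
        except (ValueError, IndexError) as exc:
            bad.append((lineno, str(exc)))
    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise FormatError(
            f"{len(bad)} malformed line(s): {detail}{more}",
            lines=[ln for ln, _ in bad],
        )
    records.sort(key=lambda r: (r.device_id, r.timestamp, r.press_index))
    return records


def _parse_row(row: list[str]) -> RawRecord:
    if len(row) != len(LOG_COLUMNS):
        raise ValueError(f"expected {len(LOG_COLUMNS)} fields, got {len(row)}")
    device_id, ts_s, xs, ys, zs, pi_s = (f.strip() for f in row)
    if not device_id:
        raise ValueError("empty device_id")
    ts = datetime.fromisoformat(ts_s)
    if ts.tzinfo is None:
        raise ValueError(f"timestamp {ts_s!r} lacks a UTC offset")
    x, y, z = float(xs), float(ys), float(zs)
    if not all(np.isfinite(v) for v in (x, y, z)):
        raise ValueError("non-finite acceleration component")
    press_index = int(pi_s)
    if press_index < 1:
        raise ValueError(f"press_index {press_index} < 1")
    return RawRecord(device_id, ts, x, y, z, press_index)


def write_log(records: Iterable[RawRecord], path_or_buffer) -> None:
    """Write records in the log dialect (fixed 6-decimal accelerations,
    millisecond timestamps), deterministically ordered."""
    recs = sorted(records, key=lambda r: (r.device_id, r.timestamp, r.press_index))
    own = not hasattr(path_or_buffer, "write")
    fh = open(path_or_buffer, "w", newline="", encoding="utf-8") if own else path_or_buffer
    try:
        fh.write(",".join(LOG_COLUMNS) + "\n")
        for r in recs:
            ts = r.timestamp.isoformat(timespec="milliseconds")
            fh.write(f"{r.device_id},{ts},{r.x:.6f},{r.y:.6f},{r.z:.6f},{r.press_index}\n")
    finally:
        if own:
            fh.close()


def log_to_text(records: Iterable[RawRecord]) -> str:
    buf = io.StringIO()
    write_log(records, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# burst grouping and classification
# ---------------------------------------------------------------------------

def group_bursts(
    records: list[RawRecord],
    gap_seconds: float = DEFAULT_BURST_GAP_S,
    *,
    angle_mode: str = "device",
) -> list[ResponseBurst]:
    """Chain consecutive same-device presses into bursts.

    Two presses belong to the same burst when their gap is at most
    ``gap_seconds``; the rule chains transitively.  ``angle_mode`` selects
    the triplet decoder: ``"device"`` (the wearable's [0, 90] transform) or
    ``"extended"`` (sign-preserving; see :mod:`paskit.angle`).
    """
    if gap_seconds <= 0:
        raise InputError("gap_seconds must be > 0")
    if angle_mode not in ("device", "extended"):
        raise InputError(f"unknown angle_mode {angle_mode!r}")
    extended = angle_mode == "extended"
    gap = timedelta(seconds=gap_seconds)
    bursts: list[ResponseBurst] = []
    run: list[RawRecord] = []

    def flush():
        if not run:
            return
        angles = tuple(accel_to_angle(r.x, r.y, r.z, extended=extended) for r in run)
        bursts.append(
            ResponseBurst(
                device_id=run[0].device_id,
                timestamp=run[0].timestamp,
                press_count=len(run),
                angles=angles,
                press_indices=tuple(r.press_index for r in run),
            )
        )
        run.clear()

    for rec in records:
        if run and (rec.device_id != run[-1].device_id or rec.timestamp - run[-1].timestamp > gap):
            flush()
        run.append(rec)
    flush()
    return bursts


def classify_and_filter(
    bursts: list[ResponseBurst],
    test_cutoff: Mapping[str, datetime] | None = None,
    *,
    familiarization_minutes: float = DEFAULT_FAMILIARIZATION_MIN,
) -> tuple[list[ResponseBurst], FilterReport]:
    """Assign categories and drop test and over-press responses.

    ``test_cutoff`` maps device ids to the end of their familiarization
    window; bursts strictly before the cutoff are test responses.  Without an
    explicit cutoff, each device's window is the ``familiarization_minutes``
    after its first burst.  After test removal, bursts of more than three
    presses are discarded; the survivors are coded 1 -> single chat,
    2 -> group chat, 3 -> baseline.

    Returns the kept bursts (with ``category`` set) and a
    :class:`FilterReport` whose totals balance by construction.
    """
    if test_cutoff is None:
        cutoff: dict[str, datetime] = {}
        for b in bursts:
            first = cutoff.get(b.device_id)
            if first is None or b.timestamp < first:
                cutoff[b.device_id] = b.timestamp
        cutoff = {
            dev: ts + timedelta(minutes=familiarization_minutes)
            for dev, ts in cutoff.items()
        }
    else:
        cutoff = dict(test_cutoff)

    kept: list[ResponseBurst] = []
    n_test = n_over = 0
    counts = {c.value: 0 for c in (Category.SINGLE_CHAT, Category.GROUP_CHAT, Category.BASELINE)}
    for b in bursts:
        dev_cut = cutoff.get(b.device_id)
        if dev_cut is not None and b.timestamp < dev_cut:
            n_test += 1
            continue
        if b.press_count > 3:
            n_over += 1
            continue
        cat = PRESS_CODING[b.press_count]
        counts[cat.value] += 1
        kept.append(
            ResponseBurst(
                device_id=b.device_id,
                timestamp=b.timestamp,
                press_count=b.press_count,
                angles=b.angles,
                category=cat,
                press_indices=b.press_indices,
            )
        )
    report = FilterReport(
        n_total=len(bursts),
        n_test_removed=n_test,
        n_over3_removed=n_over,
        n_final=len(kept),
        counts=counts,
    )
    return kept, report


def bursts_to_frame(bursts: list[ResponseBurst]) -> pd.DataFrame:
    """Tabulate bursts (one row per burst; analysis angle = first press)."""
    return pd.DataFrame(
        {
            "device_id": [b.device_id for b in bursts],
            "timestamp": [b.timestamp for b in bursts],
            "press_count": [b.press_count for b in bursts],
            "angle": [b.angle for b in bursts],
            "category": [b.category.value if b.category else "" for b in bursts],
        }
    )


# ---------------------------------------------------------------------------
# within-burst consistency
# ---------------------------------------------------------------------------

def press_consistency_icc(bursts: list[ResponseBurst]) -> float:
    """One-way random-effects ICC of within-burst press angles.

    Multi-press bursts provide repeated readings of one intended arm
    position; treating presses as interchangeable ratings of their burst,
    the ICC(1) from a one-way ANOVA (unbalanced group sizes handled with the
    usual k0 average-group-size correction) quantifies how consistently the
    sensor re-reads the angle across presses.
    """
    groups = [np.asarray(b.angles, dtype=float) for b in bursts if b.press_count >= 2]
    if len(groups) < 2:
        raise UndefinedStatisticError(
            "press-consistency ICC needs at least two multi-press bursts"
        )
    sizes = np.array([g.size for g in groups], dtype=float)
    n = len(groups)
    N = sizes.sum()
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(k * (g.mean() - grand) ** 2 for g, k in zip(groups, sizes)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (N - n)
    k0 = (N - (sizes**2).sum() / N) / (n - 1)
    denom = ms_between + (k0 - 1) * ms_within
    if denom == 0:
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    return (ms_between - ms_within) / denom
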