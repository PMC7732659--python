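"""Log parsing, burst grouping, classification and filter accounting."""

import io
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paskit.angle import angle_to_accel
from paskit.errors import FormatError, UndefinedStatisticError
from paskit.protocol import (
    Category,
    RawRecord,
    ResponseBurst,
    classify_and_filter,
    group_bursts,
    link_key,
    parse_log,
    press_consistency_icc,
    write_log,
)

TZ = timezone(timedelta(hours=1))
T0 = datetime(2019, 3, 4, 12, 0, tzinfo=TZ)


def press(dev="AA:BB:CC:DD:EE:01", t=T0, angle=45.0, idx=1):
    x, y, z = angle_to_accel(angle)
    return RawRecord(dev, t, x, y, z, idx)


def burst(dev="AA", t=T0, angles=(45.0,), category=None):
    return ResponseBurst(dev, t, len(angles), tuple(angles), category)


class TestParseLog:
    def test_empty_file(self):
        assert parse_log(io.StringIO("")) == []

    def test_round_trip(self):
        rng = np.random.default_rng(7)
        recs = [
            press(t=T0 + timedelta(seconds=5 * i), angle=float(rng.uniform(0, 90)), idx=1)
            for i in range(100)
        ]
        buf = io.StringIO()
        write_log(recs, buf)
        buf.seek(0)
        parsed = parse_log(buf)
        assert len(parsed) == 100
        assert [r.timestamp for r in parsed] == [r.timestamp for r in recs]
        assert np.allclose([r.y for r in parsed], [r.y for r in recs], atol=1e-6)

    def test_corrupted_line_reported_with_number(self):
        text = (
            "device_id,timestamp,x,y,z,press_index\n"
            "AA,2019-03-04T12:00:00+01:00,1.0,1.0,0.0,1\n"
            "AA,not-a-timestamp,1.0,1.0,0.0,1\n"
        )
        with pytest.raises(FormatError) as exc:
            parse_log(io.StringIO(text))
        assert exc.value.lines == [3]

    def test_unknown_header_rejected(self):
        with pytest.raises(FormatError):
            parse_log(io.StringIO("id,when,a,b,c,n\n"))

    def test_naive_timestamp_rejected(self):
        text = "device_id,timestamp,x,y,z,press_index\nAA,2019-03-04T12:00:00,1,1,0,1\n"
        with pytest.raises(FormatError):
            parse_log(io.StringIO(text))


class TestGroupBursts:
    def test_rapid_presses_form_one_burst(self):
        recs = [press(t=T0 + timedelta(seconds=0.5 * i), idx=i + 1) for i in range(3)]
        bursts = group_bursts(recs, 2.0)
        assert len(bursts) == 1 and bursts[0].press_count == 3

    def test_distant_presses_split(self):
        recs = [press(t=T0), press(t=T0 + timedelta(seconds=10))]
        bursts = group_bursts(recs, 2.0)
        assert [b.press_count for b in bursts] == [1, 1]

    def test_transitive_chaining(self):
        # 0 s and 3 s are farther apart than the gap, but 1.5 s bridges them
        recs = [press(t=T0 + timedelta(seconds=s)) for s in (0.0, 1.5, 3.0)]
        bursts = group_bursts(recs, 2.0)
        assert len(bursts) == 1 and bursts[0].press_count == 3

    def test_devices_never_merge(self):
        recs = sorted(
            [press(dev="AA:00:00:00:00:01"), press(dev="AA:00:00:00:00:02")],
            key=lambda r: r.device_id,
        )
        assert len(group_bursts(recs, 2.0)) == 2

    def test_analysis_angle_is_first_press(self):
        recs = [
            press(t=T0, angle=30.0),
            press(t=T0 + timedelta(seconds=0.4), angle=35.0, idx=2),
        ]
        (b,) = group_bursts(recs, 2.0)
        assert b.angle == pytest.approx(30.0, abs=1e-6)
        assert b.angles[1] == pytest.approx(35.0, abs=1e-6)


class TestClassifyAndFilter:
    def make_bursts(self):
        return [
            burst(t=T0 + timedelta(minutes=m), angles=(45.0,) * k)
            for m, k in [(0, 1), (1, 2), (2, 3), (60, 1), (61, 2), (62, 3), (63, 5)]
        ]

    def test_categories_and_test_window(self):
        kept, report = classify_and_filter(self.make_bursts())
        # first three bursts fall in the 10-minute familiarization window
        assert report.n_test_removed == 3
        assert report.n_over3_removed == 1
        assert report.n_final == 3
        assert [b.category for b in kept] == [
            Category.SINGLE_CHAT, Category.GROUP_CHAT, Category.BASELINE,
        ]

    def test_explicit_cutoff_and_overpress(self):
        bursts = [burst(t=T0, angles=(1.0,) * 5), burst(t=T0, angles=(2.0,) * 3)]
        kept, report = classify_and_filter(bursts, test_cutoff={})
        assert report.n_over3_removed == 1
        assert kept[0].category is Category.BASELINE

    @given(
        counts=st.lists(st.integers(min_value=1, max_value=6), min_size=0, max_size=40),
        cut_minutes=st.floats(min_value=0, max_value=30),
    )
    @settings(max_examples=100, derandomize=True)
    def test_filter_report_identities(self, counts, cut_minutes):
        bursts = [
            burst(t=T0 + timedelta(minutes=2.0 * i), angles=(40.0,) * k)
            for i, k in enumerate(counts)
        ]
        kept, r = classify_and_filter(bursts, familiarization_minutes=cut_minutes)
        assert r.n_final == r.n_total - r.n_test_removed - r.n_over3_removed
        assert r.n_final == sum(r.counts.values()) == len(kept)
        # conservation: every burst lands in exactly one bin
        assert r.n_total == len(bursts)

    def test_grouping_idempotent_on_burst_representation(self):
        recs = [press(t=T0 + timedelta(seconds=s)) for s in (0, 0.5, 5, 5.3, 20)]
        bursts = group_bursts(recs, 2.0)
        # re-grouping records rebuilt from burst first-presses yields same bursts
        firsts = [press(t=b.timestamp) for b in bursts]
        again = group_bursts(firsts, 2.0)
        assert [b.timestamp for b in again] == [b.timestamp for b in bursts]


class TestPressConsistencyICC:
    def test_identical_within_burst_angles(self):
        bursts = [burst(t=T0, angles=(a, a, a)) for a in (10.0, 40.0, 70.0)]
        assert press_consistency_icc(bursts) == pytest.approx(1.0)

    def test_variance_ratio_nine_to_one(self, rng):
        # between-burst variance 9x within => ICC ~ 0.9
        means = rng.normal(45, 3.0, size=400)
        bursts = [
            burst(t=T0 + timedelta(minutes=i), angles=tuple(rng.normal(m, 1.0, size=3)))
            for i, m in enumerate(means)
        ]
        assert press_consistency_icc(bursts) == pytest.approx(0.9, abs=0.03)

    def test_no_between_burst_signal(self, rng):
        bursts = [
            burst(t=T0 + timedelta(minutes=i), angles=tuple(rng.normal(45, 5, size=3)))
            for i in range(300)
        ]
        assert abs(press_consistency_icc(bursts)) < 0.1

    def test_requires_multipress_bursts(self):
        with pytest.raises(UndefinedStatisticError):
            press_consistency_icc([burst(angles=(45.0,))])


def test_link_key_uses_first_four_hex_digits():
    assert link_key("C8:3A:FF:00:12:34") == "C83A"
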