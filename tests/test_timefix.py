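"""Bulk timestamp corrections: shifts, drift, DST, day/month ambiguity."""

from datetime import datetime, timedelta

import pytest

from trapkit.schema import format_datetime, parse_datetime
from trapkit.store import FileSelection
from trapkit.timefix import (DriftSpec, DstSpec, TimeFixError, apply_dst,
                             correct_drift, flag_ambiguous_dates,
                             replay_audit, shift_times, swap_day_month)


def times(table):
    return [r.values["DateTime"] for r in table]


def all_ids(table):
    return FileSelection(table.record_ids)


def assert_only_datetime_changed(before, after):
    for b, a in zip(before, after):
        for label, value in b.values.items():
            if label != "DateTime":
                assert a.values[label] == value


class TestShift:
    def test_zero_delta_is_identity(self, table_builder):
        table = table_builder([{}, {}])
        assert times(shift_times(table, all_ids(table), 0)) == times(table)

    def test_two_hour_shift_is_exact(self, table_builder):
        table = table_builder([{}, {}, {}])
        out = shift_times(table, FileSelection([1, 3]), 7200)
        for b, a in zip(table, out):
            expected = parse_datetime(b.values["DateTime"])
            if a.record_id in (1, 3):
                expected += timedelta(hours=2)
            assert a.values["DateTime"] == format_datetime(expected)
        assert_only_datetime_changed(table, out)

    def test_shift_then_unshift_is_identity(self, table_builder):
        table = table_builder([{}, {}, {}])
        out = shift_times(shift_times(table, all_ids(table), 12345),
                          all_ids(table), -12345)
        assert times(out) == times(table)


class TestDrift:
    def test_zero_drift_is_identity(self, table_builder):
        table = table_builder([{}, {}, {}], gap_s=60)
        last = parse_datetime(table.records[-1].values["DateTime"])
        out = correct_drift(table, DriftSpec(last_correct=last))
        assert times(out) == times(table)

    def test_midpoint_gets_half_the_correction(self, table_builder):
        # t_first = T, t_last = T + 100 min, true last = T + 110 min:
        # the record at T + 50 min moves by exactly +5 min.
        table = table_builder([{}, {}, {}], gap_s=50 * 60)
        t_first = parse_datetime(table.records[0].values["DateTime"])
        out = correct_drift(table, DriftSpec(
            last_correct=t_first + timedelta(minutes=110)))
        assert parse_datetime(out.records[1].values["DateTime"]) == \
            t_first + timedelta(minutes=55)

    def test_first_anchored_last_exact(self, table_builder):
        table = table_builder([{} for _ in range(7)], gap_s=137)
        last_correct = parse_datetime(
            table.records[-1].values["DateTime"]) + timedelta(seconds=473)
        out = correct_drift(table, DriftSpec(last_correct))
        assert out.records[0].values["DateTime"] == \
            table.records[0].values["DateTime"]
        assert parse_datetime(out.records[-1].values["DateTime"]) == \
            last_correct

    def test_adjustment_is_linear_in_elapsed_time(self, table_builder):
        table = table_builder([{} for _ in range(11)], gap_s=61)
        t0 = parse_datetime(table.records[0].values["DateTime"])
        t_last = parse_datetime(table.records[-1].values["DateTime"])
        delta = 97.0
        out = correct_drift(table, DriftSpec(
            t_last + timedelta(seconds=delta)))
        span = (t_last - t0).total_seconds()
        adjustments = [
            (parse_datetime(a.values["DateTime"])
             - parse_datetime(b.values["DateTime"])).total_seconds()
            for b, a in zip(table, out)]
        import math
        for i, adj in enumerate(adjustments):
            frac = i * 61 / span
            assert adj == math.floor(delta * frac + 0.5)  # half-up rounding
        assert adjustments == sorted(adjustments)  # monotone

    def test_first_correct_override_shifts_anchor(self, table_builder):
        table = table_builder([{}, {}, {}], gap_s=60)
        t0 = parse_datetime(table.records[0].values["DateTime"])
        out = correct_drift(table, DriftSpec(
            last_correct=t0 + timedelta(seconds=240),
            first_correct=t0 + timedelta(seconds=60)))
        assert parse_datetime(out.records[0].values["DateTime"]) == \
            t0 + timedelta(seconds=60)
        assert parse_datetime(out.records[-1].values["DateTime"]) == \
            t0 + timedelta(seconds=240)

    def test_equal_endpoints_rejected(self, table_builder):
        table = table_builder([{}, {}], gap_s=60)
        table.records[1].values["DateTime"] = \
            table.records[0].values["DateTime"]
        with pytest.raises(TimeFixError, match="drift factor"):
            correct_drift(table, DriftSpec(datetime(2020, 1, 1)))


class TestDst:
    def test_forward_shifts_pivot_to_end(self, table_builder):
        table = table_builder([{} for _ in range(5)])
        out = apply_dst(table, DstSpec(pivot_id=3, direction="forward",
                                       sign=1))
        for b, a in zip(table, out):
            shift = 3600 if a.record_id >= 3 else 0
            assert parse_datetime(a.values["DateTime"]) == \
                parse_datetime(b.values["DateTime"]) \
                + timedelta(seconds=shift)

    def test_backward_shifts_start_through_pivot(self, table_builder):
        table = table_builder([{} for _ in range(5)])
        out = apply_dst(table, DstSpec(pivot_id=3, direction="backward",
                                       sign=-1))
        for b, a in zip(table, out):
            shift = -3600 if a.record_id <= 3 else 0
            assert parse_datetime(a.values["DateTime"]) == \
                parse_datetime(b.values["DateTime"]) \
                + timedelta(seconds=shift)

    def test_plus_then_minus_is_identity(self, table_builder):
        table = table_builder([{} for _ in range(4)])
        out = apply_dst(apply_dst(table, DstSpec(2, "forward", 1)),
                        DstSpec(2, "forward", -1))
        assert times(out) == times(table)

    def test_order_within_each_side_preserved(self, table_builder):
        table = table_builder([{} for _ in range(6)], gap_s=30)
        out = apply_dst(table, DstSpec(4, "forward", 1))
        stamps = times(out)
        assert stamps[:3] == sorted(stamps[:3])
        assert stamps[3:] == sorted(stamps[3:])


class TestAmbiguousDates:
    @pytest.mark.parametrize("token,expected", [
        ("02/10/2019", "ambiguous"),     # Oct 2 or Feb 10
        ("13/10/2019", "unambiguous"),   # 13 cannot be a month
        ("10/13/2019", "unambiguous"),
        ("05/05/2019", "unambiguous"),   # both readings coincide
        ("00/40/2019", "invalid"),
        ("02/10/19", "invalid"),         # two-digit year rejected
        ("2019-10-02", "invalid"),
        ("29/02/2019", "invalid"),       # 2019 is no leap year
    ])
    def test_classification(self, token, expected):
        assert flag_ambiguous_dates([token]) == [expected]

    def test_classifies_elementwise(self):
        out = flag_ambiguous_dates(["02/10/2019", "13/10/2019", "junk"])
        assert out == ["ambiguous", "unambiguous", "invalid"]


class TestSwapDayMonth:
    def test_october_2_becomes_february_10(self, table_builder):
        table = table_builder([{}])
        table.records[0].values["DateTime"] = "2019-10-02T18:30:00"
        out = swap_day_month(table, all_ids(table))
        assert out.records[0].values["DateTime"] == "2019-02-10T18:30:00"

    def test_swap_twice_is_identity(self, table_builder):
        table = table_builder([{} for _ in range(4)])
        out = swap_day_month(swap_day_month(table, all_ids(table)),
                             all_ids(table))
        assert times(out) == times(table)

    def test_day_over_12_aborts_whole_selection(self, table_builder):
        table = table_builder([{}, {}])
        table.records[1].values["DateTime"] = "2019-10-13T08:00:00"
        with pytest.raises(TimeFixError, match="13"):
            swap_day_month(table, all_ids(table))
        # nothing modified
        assert table.records[0].values["DateTime"].startswith("2019-10-02")


class TestAudit:
    def test_corrections_touch_only_datetime(self, table_builder):
        table = table_builder([{"Weather": "Sunny", "GoatCnt": "2"}
                               for _ in range(4)])
        last = parse_datetime(table.records[-1].values["DateTime"])
        out = shift_times(table, all_ids(table), 300)
        out = apply_dst(out, DstSpec(2, "forward", 1))
        out = correct_drift(out, DriftSpec(last + timedelta(seconds=4000)))
        out = swap_day_month(out, all_ids(out))
        assert_only_datetime_changed(table, out)

    def test_replaying_the_audit_reproduces_the_table(self, table_builder):
        table = table_builder([{} for _ in range(5)])
        last = parse_datetime(table.records[-1].values["DateTime"])
        out = shift_times(table, FileSelection([2, 4]), -600)
        out = apply_dst(out, DstSpec(3, "backward", -1))
        out = shift_times(out, all_ids(out), 86400)
        replayed = replay_audit(table, out.audit)
        assert times(replayed) == times(out)
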