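"""Bulk repair of the DateTime field.

Trap cameras accumulate characteristic timestamp errors: a clock that was
never set (every time off by a constant), a clock that ignores daylight
saving (a contiguous run off by an hour), a clock that drifts (error
growing linearly with elapsed time), and ambiguous day/month encodings
such as ``02/10/2019``.  Each has a bulk correction here.  All operations
touch only the DateTime column, return a new table, and append an entry
to the table's audit log; :func:`replay_audit` re-applies a log to a
pristine table and reproduces the corrected one.

Drift correction interpolates by *time*: with the first image taken as the
anchor (assumed correct, unless an explicit ``first_correct`` is given)
and the true time of the last image supplied by the analyst, every
record's adjustment is the total error scaled by its elapsed fraction
``(t_i - t_first) / (t_last - t_first)``, rounded half-up to whole
seconds.  The last image lands exactly on the supplied time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Literal

from .schema import format_datetime, parse_datetime
from .store import FileSelection, ImageTable

__all__ = [
    "DriftSpec",
    "DstSpec",
    "shift_times",
    "correct_drift",
    "apply_dst",
    "flag_ambiguous_dates",
    "swap_day_month",
    "replay_audit",
]


class TimeFixError(ValueError):
    pass


@dataclass(frozen=True)
class DriftSpec:
    """True capture time of the final image (and optionally the first)."""

    last_correct: datetime
    first_correct: datetime | None = None


@dataclass(frozen=True)
class DstSpec:
    """A daylight-saving pivot: which side shifts, and by which hour."""

    pivot_id: int
    direction: Literal["forward", "backward"] = "forward"
    sign: Literal[1, -1] = 1


def _get_dt(rec) -> datetime:
    return parse_datetime(rec.values["DateTime"])


def _set_dt(rec, dt: datetime) -> None:
    rec.values["DateTime"] = format_datetime(dt)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def shift_times(table: ImageTable, sel: FileSelection,
                delta: float) -> ImageTable:
    """Advance every selected record's DateTime by ``delta`` seconds
    (negative shifts backwards)."""
    if len(sel) == 0:
        raise TimeFixError("empty selection")
    sel.check_against(table)
    out = table.copy()
    for rec in out.records:
        if rec.record_id in sel:
            _set_dt(rec, _get_dt(rec) + timedelta(seconds=delta))
    out.audit.append({"op": "shift_times", "ids": sorted(sel.ids),
                      "delta": delta})
    return out


def correct_drift(table: ImageTable, spec: DriftSpec) -> ImageTable:
    """Linearly correct a drifting clock across the whole table.

    Requires the records' DateTimes to be time-sorted with distinct first
    and last times.  The first image keeps its time (or moves to
    ``first_correct`` when given); the last lands exactly on
    ``last_correct``; every record in between moves in proportion to its
    elapsed time since the first image.
    """
    if not table.records:
        raise TimeFixError("empty table")
    times = [_get_dt(r) for r in table.records]
    if any(b < a for a, b in zip(times, times[1:])):
        raise TimeFixError("records must be in DateTime order for drift "
                           "correction")
    t_first, t_last = times[0], times[-1]
    if t_last == t_first:
        raise TimeFixError("first and last DateTime are equal; "
                           "drift factor undefined")
    base = spec.first_correct or t_first
    offset0 = (base - t_first).total_seconds()
    delta = (spec.last_correct - t_last).total_seconds() - offset0
    span = (t_last - t_first).total_seconds()
    out = table.copy()
    for rec, t in zip(out.records, times):
        frac = (t - t_first).total_seconds() / span
        adjust = offset0 + delta * frac
        _set_dt(rec, t + timedelta(seconds=_round_half_up(adjust)))
    out.audit.append({
        "op": "correct_drift",
        "last_correct": format_datetime(spec.last_correct),
        "first_correct": (format_datetime(spec.first_correct)
                          if spec.first_correct else None)})
    return out


def apply_dst(table: ImageTable, spec: DstSpec) -> ImageTable:
    """Shift one side of a daylight-saving pivot by plus or minus an hour.

    ``forward`` shifts the pivot record and everything after it;
    ``backward`` shifts everything up to and including the pivot.
    """
    if spec.direction not in ("forward", "backward"):
        raise TimeFixError(f"bad direction {spec.direction!r}")
    if spec.sign not in (1, -1):
        raise TimeFixError(f"sign must be +1 or -1 (hours), got {spec.sign}")
    k = table.index_of(spec.pivot_id)
    delta = timedelta(hours=spec.sign)
    out = table.copy()
    affected = (out.records[k:] if spec.direction == "forward"
                else out.records[: k + 1])
    for rec in affected:
        _set_dt(rec, _get_dt(rec) + delta)
    out.audit.append({"op": "apply_dst", "pivot_id": spec.pivot_id,
                      "direction": spec.direction, "sign": spec.sign})
    return out


def _classify_date_token(token: str) -> str:
    parts = token.split("/")
    if len(parts) != 3:
        return "invalid"
    a_s, b_s, y_s = parts
    if not (a_s.isdigit() and b_s.isdigit() and y_s.isdigit()):
        return "invalid"
    if len(y_s) != 4:  # two-digit years are rejected, never guessed
        return "invalid"
    a, b, year = int(a_s), int(b_s), int(y_s)

    def valid(day: int, month: int) -> bool:
        try:
            datetime(year, month, day)
        except ValueError:
            return False
        return True

    day_first = valid(a, b)   # a = day, b = month
    month_first = valid(b, a)  # a = month, b = day
    if day_first and month_first:
        # both readings are calendar-valid; identical only when a == b
        return "unambiguous" if a == b else "ambiguous"
    if day_first or month_first:
        return "unambiguous"
    return "invalid"


def flag_ambiguous_dates(raw_dates: list[str]) -> list[str]:
    """Classify ``a/b/yyyy`` date texts.

    Returns, per input, one of ``"unambiguous"`` (exactly one of the
    day-first / month-first readings is a valid calendar date, or both
    readings coincide), ``"ambiguous"`` (both readings valid and
    different, i.e. day and month are both <= 12), or ``"invalid"``
    (neither reading valid, or not an ``a/b/yyyy`` token at all).
    """
    return [_classify_date_token(t) for t in raw_dates]


def swap_day_month(table: ImageTable, sel: FileSelection) -> ImageTable:
    """Exchange day and month of every selected DateTime (the fix for a
    camera that wrote dates in the other order).  Involution.  If any
    selected date has day > 12 the swap is impossible and nothing is
    modified."""
    if len(sel) == 0:
        raise TimeFixError("empty selection")
    sel.check_against(table)
    swapped: dict[int, datetime] = {}
    for rec in table.records:
        if rec.record_id not in sel:
            continue
        t = _get_dt(rec)
        if t.day > 12:
            raise TimeFixError(
                f"record {rec.record_id}: day {t.day} cannot be a month; "
                "nothing modified")
        swapped[rec.record_id] = t.replace(month=t.day, day=t.month)
    out = table.copy()
    for rec in out.records:
        if rec.record_id in swapped:
            _set_dt(rec, swapped[rec.record_id])
    out.audit.append({"op": "swap_day_month", "ids": sorted(sel.ids)})
    return out


def replay_audit(table: ImageTable, audit: list[dict]) -> ImageTable:
    """Re-apply a recorded audit log to ``table`` (time operations only)."""
    out = table
    for entry in audit:
        op = entry["op"]
        if op == "shift_times":
            out = shift_times(out, FileSelection(entry["ids"]),
                              entry["delta"])
        elif op == "correct_drift":
            first = (parse_datetime(entry["first_correct"])
                     if entry.get("first_correct") else None)
            out = correct_drift(
                out, DriftSpec(parse_datetime(entry["last_correct"]), first))
        elif op == "apply_dst":
            out = apply_dst(out, DstSpec(entry["pivot_id"],
                                         entry["direction"], entry["sign"]))
        elif op == "swap_day_month":
            out = swap_day_month(out, FileSelection(entry["ids"]))
        else:
            raise TimeFixError(f"unknown audit op {op!r}")
    return out
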