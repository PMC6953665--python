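"""Bulk-repair camera timestamp errors: constant offset, clock drift and
day/month ambiguity.

The camera below ran 10 minutes slow by the end of a 100-minute
deployment; drift correction anchors the first image and spreads the
error linearly over elapsed time."""

from datetime import datetime, timedelta

from trapkit.schema import format_datetime, new_record, parse_datetime
from trapkit.store import FileSelection, ImageRecord, ImageTable
from trapkit.synthgen import generate_template_example
from trapkit.timefix import (DriftSpec, correct_drift, flag_ambiguous_dates,
                             shift_times, swap_day_month)

schema = generate_template_example()
start = datetime(2019, 10, 2, 6, 0, 0)
records = []
for i, minutes in enumerate([0, 50, 100]):
    values = new_record(schema)
    values.update(File=f"Img{i + 1}.jpg", RelativePath="Station1",
                  DateTime=format_datetime(start
                                           + timedelta(minutes=minutes)))
    records.append(ImageRecord(i + 1, values))
table = ImageTable(schema, records)

# the analyst knows the LAST image was really taken 10 minutes later
truth = start + timedelta(minutes=110)
fixed = correct_drift(table, DriftSpec(last_correct=truth))
for before, after in zip(table, fixed):
    print(before.values["DateTime"], "->", after.values["DateTime"])
# first unchanged, midpoint +5 min, last +10 min: linear in elapsed time

# a camera set an hour wrong is a plain shift
shifted = shift_times(fixed, FileSelection(fixed.record_ids), 3600)
print("after +1 h:", shifted.records[0].values["DateTime"])

# 02/10/2019 could be 2 October or 10 February; 13/10/2019 cannot
print(flag_ambiguous_dates(["02/10/2019", "13/10/2019", "00/40/2019"]))
swapped = swap_day_month(shifted, FileSelection(shifted.record_ids))
print("day/month swapped:", swapped.records[0].values["DateTime"])
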