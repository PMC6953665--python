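"""Repetitive-entry operators: backfill, copy-previous, QuickPaste and
text prediction.

Weather rarely changes between consecutive images, so the analyst enters
'Sunny' once and backfills the run instead of retyping it."""

from datetime import datetime, timedelta

from trapkit.editops import (PredictionHistory, QuickPasteEntry,
                             apply_quickpaste, copy_previous_values,
                             predict_text, propagate_field)
from trapkit.schema import format_datetime, new_record
from trapkit.store import ImageRecord, ImageTable
from trapkit.synthgen import generate_template_example

schema = generate_template_example()
records = []
for i in range(6):
    values = new_record(schema)
    values.update(File=f"Img{i + 1}.jpg", RelativePath="Station1",
                  DateTime=format_datetime(datetime(2019, 10, 2, 6)
                                           + timedelta(minutes=i)))
    records.append(ImageRecord(i + 1, values))
table = ImageTable(schema, records)

# enter Sunny on image 1, skip ahead to image 5, backfill the gap
table.records[0].values["Weather"] = "Sunny"
table = propagate_field(table, 5, "Weather", "backfill")
print("after backfill:", [r.values["Weather"] for r in table])

# copy the previous image's copyable fields onto image 6
table.records[4].values["GoatCnt"] = "2"
table = copy_previous_values(table, 6)
print("image 6 goats:", table.records[5].values["GoatCnt"])

# one click pastes a whole named pattern
entry = QuickPasteEntry("No goats, sunny", {
    "GoatCnt": "0", "Weather": "Sunny", "Analyst": "Saul",
    "Comments": "nothing to see", "Publicity": "false"})
table = apply_quickpaste(table, 6, entry)
print("image 6 after quickpaste:",
      {k: table.records[5].values[k] for k in entry.assignments})

# Notes learn from what was previously committed
history = PredictionHistory(schema)
history.commit("Comments", "Overcast")
print("typing 'O' predicts:", predict_text(history, "Comments", "O"))
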