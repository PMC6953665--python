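"""Type-aware selection, two-key sorting and filename find.

A query is a flat list of per-field criteria under one AND/OR; it is
compiled to parameterized SQL and run against the record database."""

from datetime import datetime, timedelta

from trapkit.queries import (Criterion, Query, SortKey, compile_query,
                             find_next, select_files, sort_files)
from trapkit.schema import format_datetime, new_record
from trapkit.store import ImageRecord, ImageTable
from trapkit.synthgen import generate_template_example

schema = generate_template_example()
rows = [("Img01.jpg", "2", "1", "Sunny"), ("Img02.jpg", "0", "5", "Cloudy"),
        ("Img03.jpg", "3", "0", "Sunny"), ("Img04.jpg", "1", "2", "Foggy"),
        ("Img05.jpg", "0", "0", "Sunny")]
records = []
for i, (name, goats, hikers, weather) in enumerate(rows):
    values = new_record(schema)
    values.update(File=name, RelativePath="Station1",
                  DateTime=format_datetime(datetime(2019, 10, 2, 6)
                                           + timedelta(minutes=i)),
                  GoatCnt=goats, Hikers=hikers, Weather=weather)
    records.append(ImageRecord(i + 1, values))
table = ImageTable(schema, records)

# goats AND hikers both present
q = Query((Criterion("GoatCnt", ">", "0"), Criterion("Hikers", ">", "0")),
          "AND")
where, params = compile_query(q, schema)
print("compiled WHERE:", where, params)
sel = select_files(table, q)
print("matches:", sorted(table.record(i).values["File"] for i in sel.ids))

# sort by weather, then by goat count (numeric, not lexicographic)
ordered = sort_files(table, SortKey("Weather", "GoatCnt"))
print("sorted:", [(r.values["Weather"], r.values["GoatCnt"])
                  for r in ordered])

# step through file names containing '0' from record 3 onwards
print("find next '05' after Img03:",
      table.record(find_next(table, 3, "05")).values["File"])
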