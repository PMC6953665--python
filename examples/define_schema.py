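"""Define a project schema and see type-constrained entry in action.

Builds the goat/hiker trail-survey template, writes it to JSON, and shows
which raw values each field type accepts."""

import tempfile
from pathlib import Path

from trapkit.schema import is_valid, new_record, write_template
from trapkit.synthgen import generate_template_example

schema = generate_template_example()
write_template(schema, Path(tempfile.mkdtemp()) / "template.json")
print("fields:", ", ".join(schema.data_labels))

# a fresh record starts at the template defaults
print("new record:", new_record(schema))

# each field only accepts values legal for its type
for label, raw in [("GoatCnt", "3"), ("GoatCnt", "-1"),
                   ("Weather", "Sunny"), ("Weather", "Drizzle"),
                   ("Publicity", "true"), ("Publicity", "Yes")]:
    verdict = "accepted" if is_valid(schema[label], raw) else "rejected"
    print(f"{label} := {raw!r}: {verdict}")

# Accepted values are the only ones that can ever reach the database, so
# downstream analysis never meets a malformed count, choice or flag.
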