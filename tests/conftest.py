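"""Shared fixtures: the example survey schema, hand-built record tables,
and a generated synthetic image set reused across tests."""

from __future__ import annotations

from datetime import datetime, timedelta
from pathlib import Path

import pytest

from trapkit import store
from trapkit.schema import format_datetime, new_record
from trapkit.store import ImageRecord, ImageTable
from trapkit.synthgen import (SyntheticSpec, generate_image_set,
                              generate_template_example)


@pytest.fixture(scope="session")
def survey_schema():
    """The goat/hiker trail-survey schema used throughout."""
    return generate_template_example()


def build_table(schema, rows, start=datetime(2019, 10, 2, 6, 0, 0),
                gap_s=60):
    """A table of ``len(rows)`` records one minute apart; each row is a
    dict of user-field overrides."""
    records = []
    for i, overrides in enumerate(rows):
        values = new_record(schema)
        values["File"] = f"Img{i + 1:03d}.jpg"
        values["RelativePath"] = "Station1"
        values["DateTime"] = format_datetime(
            start + timedelta(seconds=i * gap_s))
        values.update(overrides)
        records.append(ImageRecord(i + 1, values))
    return ImageTable(schema, records, Path("."))


@pytest.fixture
def table_builder(survey_schema):
    return lambda rows, **kw: build_table(survey_schema, rows, **kw)


@pytest.fixture(scope="session")
def synth_set(tmp_path_factory, survey_schema):
    """One generated image set (seed 7) scanned into a table."""
    out = tmp_path_factory.mktemp("synthset")
    spec = SyntheticSpec(seed=7)
    truth = generate_image_set(spec, out)
    table = store.scan_image_set(out, survey_schema)
    return spec, truth, table, out
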