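"""Import recognizer output and keep only confident detections.

A detector (e.g. MegaDetector) emits per-file candidate boxes with
confidences; the analyst chooses a threshold and reviews only images
with a confident animal/person/vehicle in them."""

import json
import tempfile
from pathlib import Path

from trapkit.detections import filter_detections, load_detections

doc = {"images": [
    {"file": "Station1/Img001.jpg", "detections": [
        {"category": "1", "conf": 0.93, "bbox": [0.41, 0.52, 0.10, 0.08]},
        {"category": "1", "conf": 0.22, "bbox": [0.70, 0.30, 0.05, 0.05]},
    ]},
    {"file": "Station1/Img002.jpg", "detections": [
        {"category": "2", "conf": 0.88, "bbox": [0.10, 0.10, 0.20, 0.60]},
    ]},
    {"file": "Station1/Img003.jpg", "detections": []},
]}
path = Path(tempfile.mkdtemp()) / "md.json"
path.write_text(json.dumps(doc))

ds = load_detections(path)
print(f"loaded {len(ds)} detections over {len(ds.by_file)} files")
confident = filter_detections(ds, threshold=0.8)
for file, dets in confident.by_file.items():
    for d in dets:
        print(f"{file}: {d.category} at confidence {d.confidence}")
print(f"{len(confident)} detections survive the 0.8 threshold")
# The low-confidence 0.22 box is dropped; files keep their (possibly
# empty) entries so joining against the record table is unaffected.
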