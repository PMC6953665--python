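"""Group time-ordered images into episodes and label each image's position.

A motion-triggered camera fires in bursts while an animal moves through
the scene, so one event spreads over many images.  To avoid double
counting, analysts treat a maximal run of images whose successive
inter-image gaps do not exceed a configurable interval as one *episode*
and typically enter counts on a single image of it.  Each image is
annotated ``i/n`` within its episode, or ``Single`` when it stands alone.

Grouping runs over the whole image set in time order regardless of any
active selection (``per_folder=True`` restricts runs to images from the
same folder, for sets that interleave several stations in time).
The boundary is inclusive: a gap exactly equal to the threshold stays
within the episode.
"""

from __future__ import annotations

from dataclasses import dataclass

from .schema import FieldType, parse_datetime
from .store import ImageTable

__all__ = ["Episode", "EpisodeLabel", "group_episodes", "label_episodes",
           "write_episode_labels"]


class EpisodeError(ValueError):
    pass


@dataclass(frozen=True)
class Episode:
    """A maximal time-contiguous run of records."""

    member_ids: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "member_ids", tuple(self.member_ids))
        if not self.member_ids:
            raise EpisodeError("an episode needs at least one member")

    @property
    def start_id(self) -> int:
        return self.member_ids[0]

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class EpisodeLabel:
    """A record's position annotation: ``"i/n"`` or ``"Single"``."""

    record_id: int
    position: int
    size: int

    @property
    def text(self) -> str:
        return "Single" if self.size == 1 else f"{self.position}/{self.size}"


def _time_order(table: ImageTable):
    def sort_key(rec):
        return (rec.values["DateTime"], rec.values["RelativePath"],
                rec.values["File"])
    return sorted(table.records, key=sort_key)


def group_episodes(table: ImageTable, threshold: float,
                   per_folder: bool = False) -> list[Episode]:
    """Partition all records into episodes by inter-image gap.

    Records are time-sorted (ties broken by path) and a new episode starts
    whenever the gap to the previous record exceeds ``threshold`` seconds.
    ``math.inf`` is a legal threshold (one episode of everything).
    With ``per_folder``, records are grouped within their folder only.
    """
    if not threshold > 0:
        raise EpisodeError("threshold must be positive")
    ordered = _time_order(table)
    groups: dict[str, list] = {}
    for rec in ordered:
        folder = rec.values["RelativePath"] if per_folder else ""
        groups.setdefault(folder, []).append(rec)

    episodes = []
    for recs in groups.values():
        current = [recs[0].record_id]
        prev_t = parse_datetime(recs[0].values["DateTime"])
        for rec in recs[1:]:
            t = parse_datetime(rec.values["DateTime"])
            if (t - prev_t).total_seconds() > threshold:
                episodes.append(Episode(tuple(current)))
                current = []
            current.append(rec.record_id)
            prev_t = t
        episodes.append(Episode(tuple(current)))
    # present episodes in start-time order across folders
    start_time = {e.start_id: table.record(e.start_id).values["DateTime"]
                  for e in episodes}
    episodes.sort(key=lambda e: (start_time[e.start_id], e.start_id))
    return episodes


def label_episodes(episodes: list[Episode]) -> list[EpisodeLabel]:
    """One label per record: ``1/n`` ... ``n/n``, or ``Single``.

    The episodes must be disjoint (a partition of whatever set they
    cover); an id in two episodes is an error.
    """
    seen: set[int] = set()
    labels = []
    for ep in episodes:
        for pos, rid in enumerate(ep.member_ids, start=1):
            if rid in seen:
                raise EpisodeError(f"record {rid} appears in two episodes")
            seen.add(rid)
            labels.append(EpisodeLabel(rid, pos, len(ep)))
    return labels


def write_episode_labels(table: ImageTable, labels: list[EpisodeLabel],
                         data_label: str) -> ImageTable:
    """Store each record's label text into a Note field."""
    if table.schema[data_label].field_type is not FieldType.NOTE:
        raise EpisodeError(f"{data_label!r} must be a Note field")
    by_id = {lab.record_id: lab.text for lab in labels}
    out = table.copy()
    for rec in out.records:
        if rec.record_id in by_id:
            rec.values[data_label] = by_id[rec.record_id]
    return out
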