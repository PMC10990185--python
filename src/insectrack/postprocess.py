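"""Metadata post-processing: per-image rows -> one row per tracked insect.

A tracked individual accumulates one classified image roughly every second
while present, and the classifier can disagree with itself across those
images. Per track, each candidate class is scored by its *weighted mean
classification probability*::

    score(c) = mean(top-1 prob of images labelled c) * n_images(c) / n_images(track)

and the argmax becomes the track's final class. Tracks with fewer than
``min_images`` (default 3, i.e. tracked for slightly over two seconds at
~1 s capture frequency) or more than ``max_images`` (default 1800, i.e.
tracked for ~30-40 min — almost always non-insect detections such as
fallen leaves) are excluded. Bounding boxes convert to millimeters via the
known physical platform dimensions. To flag likely re-entries of the same
individual, each track's start time is compared against the end times of
the previous few same-class tracks; a gap under the threshold (default
5 s) marks the track as a possible duplicate. Activity is reported as
unique tracking IDs per hour of active recording.
"""

from __future__ import annotations

import math
from collections import defaultdict, deque
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .metadata_io import ClassifiedRecord

__all__ = [
    "PostprocessConfig",
    "TrackSummary",
    "SummaryReport",
    "ActivityRate",
    "NON_INSECT_CLASSES",
    "weighted_class_probabilities",
    "assign_top1",
    "filter_tracks",
    "bbox_size_mm",
    "dedup_gap",
    "activity_rate",
    "summarize",
    "write_summaries",
    "read_summaries",
]

#: Classes that represent non-insect detections (background, birds, dirt,
#: shadows); kept in summaries but excluded from activity/abundance counts.
NON_INSECT_CLASSES = frozenset({"none_bg", "none_bird", "none_dirt", "none_shadow"})


@dataclass(frozen=True)
class PostprocessConfig:
    min_images: int = 3
    max_images: int = 1800
    dedup_window: int = 5
    dedup_threshold: float = 5.0
    platform_size_mm: tuple[float, float] = (350.0, 200.0)
    non_insect_classes: frozenset[str] = NON_INSECT_CLASSES

    def __post_init__(self):
        if not (1 <= self.min_images <= self.max_images):
            raise ValueError(
                f"need 1 <= min_images <= max_images, got {self.min_images}, {self.max_images}"
            )
        if self.dedup_window < 1:
            raise ValueError("dedup_window must be >= 1")


@dataclass
class TrackSummary:
    """One row of the final per-individual metadata file."""

    recording_id: str
    track_id: int
    top1_class: str
    top1_weighted_prob: float
    n_images: int
    start_time: float
    end_time: float
    width_mm: float
    height_mm: float
    tie_flag: bool = False
    prev_same_class_gap_s: float | None = None
    dedup_flag: bool = False

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.start_time > self.end_time:
            raise ValueError("start_time must be <= end_time")
        if not (0.0 < self.top1_weighted_prob <= 1.0):
            raise ValueError("top1_weighted_prob must be in (0, 1]")
        if self.width_mm < 0 or self.height_mm < 0:
            raise ValueError("bbox sizes must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.end_time - self.start_time


def weighted_class_probabilities(
    records: Sequence[ClassifiedRecord],
) -> dict[str, float]:
    """Weighted mean classification probability per candidate class.

    For each class occurring as a top-1 label among the track's images:
    mean top-1 probability of that class times the share of the track's
    images classified to it. Classes never occurring map to 0 implicitly.
    """
    if not records:
        raise ValueError("empty record set for a track")
    totals: dict[str, float] = defaultdict(float)
    counts: dict[str, int] = defaultdict(int)
    for rec in records:
        totals[rec.top1_class] += rec.top1_prob
        counts[rec.top1_class] += 1
    n = len(records)
    return {
        cls: (totals[cls] / counts[cls]) * (counts[cls] / n) for cls in totals
    }


def assign_top1(records: Sequence[ClassifiedRecord]) -> tuple[str, float, bool]:
    """Final class of one track: argmax of the weighted mean probabilities.

    Exact ties break to the lexicographically smallest class; the returned
    flag records that a tie occurred.
    """
    scores = weighted_class_probabilities(records)
    best = max(scores.values())
    winners = sorted(cls for cls, s in scores.items() if s == best)
    return winners[0], best, len(winners) > 1


def filter_tracks(
    summaries: Sequence[TrackSummary], config: PostprocessConfig
) -> tuple[list[TrackSummary], list[TrackSummary], list[TrackSummary]]:
    """Partition tracks into (kept, removed_below, removed_above) by image count.

    A track is kept iff ``min_images <= n_images <= max_images``; the
    partition is exact (every summary lands in exactly one bucket).
    """
    kept, below, above = [], [], []
    for s in summaries:
        if s.n_images < config.min_images:
            below.append(s)
        elif s.n_images > config.max_images:
            above.append(s)
        else:
            kept.append(s)
    return kept, below, above


def bbox_size_mm(
    bbox: Sequence[float], platform_size_mm: tuple[float, float]
) -> tuple[float, float]:
    """Convert a normalized box to physical millimeters on the platform."""
    pw, ph = platform_size_mm
    if pw <= 0 or ph <= 0:
        raise ValueError("platform dimensions must be > 0")
    return ((bbox[2] - bbox[0]) * pw, (bbox[3] - bbox[1]) * ph)


def dedup_gap(
    summaries: Sequence[TrackSummary], config: PostprocessConfig
) -> tuple[list[TrackSummary], int]:
    """Minimum time gap to recent previous same-class tracks; flag re-entries.

    Summaries are processed in start-time order. For each one, the gap is
    the minimum of ``start_time - previous.end_time`` over the up to
    ``dedup_window`` most recent earlier tracks sharing its final class
    (undefined for the first of a class). Tracks with a gap below
    ``dedup_threshold`` are flagged as possible re-entries of the same
    individual; the flagged count is returned alongside.
    """
    ordered = sorted(summaries, key=lambda s: (s.start_time, s.recording_id, s.track_id))
    recent: dict[str, deque[TrackSummary]] = defaultdict(
        lambda: deque(maxlen=config.dedup_window)
    )
    out: list[TrackSummary] = []
    n_flagged = 0
    for s in ordered:
        prev = recent[s.top1_class]
        gap = min((s.start_time - p.end_time for p in prev), default=None)
        flagged = gap is not None and gap < config.dedup_threshold
        n_flagged += flagged
        out.append(replace(s, prev_same_class_gap_s=gap, dedup_flag=flagged))
        recent[s.top1_class].append(out[-1])
    return out, n_flagged


@dataclass(frozen=True)
class ActivityRate:
    """Unique tracking IDs per hour of active recording."""

    exact: float
    reported: int  # half-up rounded value


def activity_rate(n_ids: int, recording_minutes: float) -> ActivityRate:
    """Extrapolate an ID count over a recording interval to IDs per hour.

    The exact rate ``n_ids * 60 / recording_minutes`` is retained; the
    reported value rounds half-up to an integer (e.g. 41 IDs in 40 min ->
    61.5 -> 62).
    """
    if recording_minutes <= 0:
        raise ValueError("recording_minutes must be > 0")
    exact = n_ids * 60.0 / recording_minutes
    return ActivityRate(exact=exact, reported=int(math.floor(exact + 0.5)))


@dataclass
class SummaryReport:
    """Kept per-track summaries plus removal/flag accounting."""

    kept: list[TrackSummary]
    n_total: int
    n_removed_below: int
    n_removed_above: int
    n_flagged: int
    n_insect_kept: int
    flagged_share_pct: float | None  # flagged % of kept insect-class tracks

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def summarize(
    records: Sequence[ClassifiedRecord], config: PostprocessConfig | None = None
) -> SummaryReport:
    """Full post-processing: group, classify, filter, size, deduplicate.

    Records are grouped by the composite ``(recording_id, track_id)``
    identity; each group becomes one :class:`TrackSummary` carrying the
    weighted-probability final class, image count, presence interval, and
    mean bounding-box size in millimeters. Tracks outside the image-count
    bounds are removed, then re-entry gaps are computed over the kept
    tracks. The flagged share is reported over kept insect-class tracks
    only (non-insect classes stay in the output but are not counted).
    Output is invariant to input row order.
    """
    config = config or PostprocessConfig()
    groups: dict[tuple[str, int], list[ClassifiedRecord]] = defaultdict(list)
    for rec in records:
        if not isinstance(rec, ClassifiedRecord):
            raise TypeError("summarize requires classified records")
        groups[(rec.recording_id, rec.track_id)].append(rec)

    summaries: list[TrackSummary] = []
    for (recording_id, track_id), recs in sorted(groups.items()):
        recs = sorted(recs, key=lambda r: r.timestamp)
        cls, prob, tie = assign_top1(recs)
        mean_bbox = [
            sum(r.bbox[i] for r in recs) / len(recs) for i in range(4)
        ]
        width_mm, height_mm = bbox_size_mm(mean_bbox, config.platform_size_mm)
        summaries.append(
            TrackSummary(
                recording_id=recording_id,
                track_id=track_id,
                top1_class=cls,
                top1_weighted_prob=prob,
                n_images=len(recs),
                start_time=recs[0].timestamp,
                end_time=recs[-1].timestamp,
                width_mm=width_mm,
                height_mm=height_mm,
                tie_flag=tie,
            )
        )

    kept, below, above = filter_tracks(summaries, config)
    kept, _ = dedup_gap(kept, config)
    insect_kept = [s for s in kept if s.top1_class not in config.non_insect_classes]
    n_flagged = sum(s.dedup_flag for s in insect_kept)
    share = 100.0 * n_flagged / len(insect_kept) if insect_kept else None
    return SummaryReport(
        kept=kept,
        n_total=len(summaries),
        n_removed_below=len(below),
        n_removed_above=len(above),
        n_flagged=n_flagged,
        n_insect_kept=len(insect_kept),
        flagged_share_pct=share,
    )


_SUMMARY_COLUMNS = [
    "recording_id",
    "track_id",
    "top1_class",
    "top1_weighted_prob",
    "n_images",
    "start_time",
    "end_time",
    "duration_s",
    "width_mm",
    "height_mm",
    "prev_same_class_gap_s",
    "dedup_flag",
    "tie_flag",
]


def write_summaries(summaries: Sequence[TrackSummary], path: str | Path) -> Path:
    """Write the final per-individual summary CSV."""
    rows = [
        {
            "recording_id": s.recording_id,
            "track_id": s.track_id,
            "top1_class": s.top1_class,
            "top1_weighted_prob": s.top1_weighted_prob,
            "n_images": s.n_images,
            "start_time": s.start_time,
            "end_time": s.end_time,
            "duration_s": s.duration_s,
            "width_mm": s.width_mm,
            "height_mm": s.height_mm,
            "prev_same_class_gap_s": s.prev_same_class_gap_s,
            "dedup_flag": s.dedup_flag,
            "tie_flag": s.tie_flag,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_summaries(path: str | Path) -> pd.DataFrame:
    """Load a summary CSV back into a DataFrame."""
    return pd.read_csv(path)
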