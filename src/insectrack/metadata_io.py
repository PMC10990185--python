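"""Camera-trap metadata CSV I/O.

The on-device pipeline saves one row per captured insect image: which
recording interval it belongs to, when it was taken, which tracking ID it
was assigned, the detector's label and confidence, and the normalized
bounding box on the frame. A later classification step appends the top-3
predicted classes and probabilities as extra columns. This module reads,
validates, writes and merges both variants of that schema.

Tracking IDs are only unique within one recording interval (the on-device
tracker restarts for every scheduled recording), so the identity of a
tracked individual is always the composite key ``(recording_id, track_id)``.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Sequence

__all__ = [
    "MetadataRecord",
    "ClassifiedRecord",
    "SchemaError",
    "RowError",
    "RAW_COLUMNS",
    "CLASSIFIED_COLUMNS",
    "NULL_CLASS",
    "read_metadata",
    "write_metadata",
    "merge_metadata",
]

#: Fixed column order of the raw per-image metadata CSV.
RAW_COLUMNS = (
    "recording_id",
    "timestamp",
    "track_id",
    "label",
    "confidence",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "crop_path",
)

#: Columns appended by the classification step (top-3 classes + probabilities).
CLASSIFIED_EXTRA = (
    "top1_class",
    "top1_prob",
    "top2_class",
    "top2_prob",
    "top3_class",
    "top3_prob",
)

CLASSIFIED_COLUMNS = RAW_COLUMNS + CLASSIFIED_EXTRA

#: Reserved padding class used when a classifier returns fewer than 3 classes.
NULL_CLASS = "_null_"

Schema = Literal["raw", "classified"]


class SchemaError(ValueError):
    """The CSV header does not match the expected schema."""


class RowError(ValueError):
    """A data row could not be parsed or violates a record invariant."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


@dataclass(frozen=True)
class MetadataRecord:
    """One saved cropped-image row of the camera-trap output.

    Timestamps are absolute seconds (Unix epoch) and are rounded to
    millisecond precision on construction, matching the ISO-8601
    millisecond serialization so that write/read round-trips are exact.
    """

    recording_id: str
    timestamp: float
    track_id: int
    label: str
    confidence: float
    bbox: tuple[float, float, float, float]
    crop_path: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "timestamp", round(float(self.timestamp), 3))
        object.__setattr__(self, "bbox", tuple(float(v) for v in self.bbox))
        object.__setattr__(self, "confidence", float(self.confidence))
        object.__setattr__(self, "track_id", int(self.track_id))
        self.validate()

    def validate(self) -> None:
        x_min, y_min, x_max, y_max = self.bbox
        for name, v in zip(("x_min", "y_min", "x_max", "y_max"), self.bbox):
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValueError(f"{name}={v} outside normalized range [0, 1]")
        if not x_min < x_max:
            raise ValueError(f"x_min={x_min} not < x_max={x_max}")
        if not y_min < y_max:
            raise ValueError(f"y_min={y_min} not < y_max={y_max}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence={self.confidence} outside [0, 1]")
        if self.track_id <= 0:
            raise ValueError(f"track_id={self.track_id} must be positive")


@dataclass(frozen=True)
class ClassifiedRecord(MetadataRecord):
    """Metadata row with appended top-3 classification results.

    ``top_classes``/``top_probs`` always have length 3; shorter classifier
    outputs are padded with :data:`NULL_CLASS` at probability 0.
    """

    top_classes: tuple[str, str, str] = (NULL_CLASS, NULL_CLASS, NULL_CLASS)
    top_probs: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        classes = list(self.top_classes)
        probs = [float(p) for p in self.top_probs]
        if len(classes) != len(probs):
            raise ValueError("top_classes and top_probs length mismatch")
        while len(classes) < 3:
            classes.append(NULL_CLASS)
            probs.append(0.0)
        if len(classes) > 3:
            raise ValueError("more than 3 top classes")
        object.__setattr__(self, "top_classes", tuple(classes))
        object.__setattr__(self, "top_probs", tuple(probs))
        super().__post_init__()

    def validate(self) -> None:
        super().validate()
        for p in self.top_probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"classification probability {p} outside [0, 1]")
        if any(a < b for a, b in zip(self.top_probs, self.top_probs[1:])):
            raise ValueError(f"top_probs not non-increasing: {self.top_probs}")

    @property
    def top1_class(self) -> str:
        return self.top_classes[0]

    @property
    def top1_prob(self) -> float:
        return self.top_probs[0]


# -- serialization helpers ---------------------------------------------------

_EPOCH = datetime(1970, 1, 1, tzinfo=timezone.utc)


def format_timestamp(seconds: float) -> str:
    """Epoch seconds -> ISO-8601 UTC with millisecond precision."""
    dt = datetime.fromtimestamp(round(seconds, 3), tz=timezone.utc)
    return dt.strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"


def parse_timestamp(text: str) -> float:
    dt = datetime.strptime(text, "%Y-%m-%dT%H:%M:%S.%fZ").replace(tzinfo=timezone.utc)
    return round((dt - _EPOCH).total_seconds(), 3)


def _fmt_float(x: float) -> str:
    # repr gives the shortest string that parses back to the same float
    return repr(float(x))


def _record_to_row(rec: MetadataRecord) -> list[str]:
    row = [
        rec.recording_id,
        format_timestamp(rec.timestamp),
        str(rec.track_id),
        rec.label,
        _fmt_float(rec.confidence),
        *(_fmt_float(v) for v in rec.bbox),
        rec.crop_path or "",
    ]
    if isinstance(rec, ClassifiedRecord):
        for cls, prob in zip(rec.top_classes, rec.top_probs):
            row.extend([cls, _fmt_float(prob)])
    return row


def _parse_row(row: dict[str, str], schema: Schema, row_index: int) -> MetadataRecord:
    def _float(column: str) -> float:
        try:
            return float(row[column])
        except ValueError:
            raise RowError(row_index, f"unparseable value {row[column]!r} in column {column!r}")

    try:
        timestamp = parse_timestamp(row["timestamp"])
    except ValueError:
        raise RowError(row_index, f"unparseable timestamp {row['timestamp']!r}")
    try:
        track_id = int(row["track_id"])
    except ValueError:
        raise RowError(row_index, f"unparseable track_id {row['track_id']!r}")

    common = dict(
        recording_id=row["recording_id"],
        timestamp=timestamp,
        track_id=track_id,
        label=row["label"],
        confidence=_float("confidence"),
        bbox=(_float("x_min"), _float("y_min"), _float("x_max"), _float("y_max")),
        crop_path=row["crop_path"] or None,
    )
    try:
        if schema == "classified":
            return ClassifiedRecord(
                **common,
                top_classes=(row["top1_class"], row["top2_class"], row["top3_class"]),
                top_probs=(_float("top1_prob"), _float("top2_prob"), _float("top3_prob")),
            )
        return MetadataRecord(**common)
    except ValueError as exc:
        raise RowError(row_index, str(exc)) from exc


def _columns_for(schema: Schema) -> tuple[str, ...]:
    if schema == "raw":
        return RAW_COLUMNS
    if schema == "classified":
        return CLASSIFIED_COLUMNS
    raise ValueError(f"unknown schema {schema!r}")


def detect_schema(path: str | Path) -> Schema:
    """Infer raw vs classified schema from a file's header row."""
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh), None)
    if header is None:
        raise SchemaError(f"{path}: empty file, no header")
    if tuple(header) == CLASSIFIED_COLUMNS:
        return "classified"
    if tuple(header) == RAW_COLUMNS:
        return "raw"
    raise SchemaError(f"{path}: unrecognized header {header}")


def read_metadata(path: str | Path, schema: Schema = "raw") -> list[MetadataRecord]:
    """Read a metadata CSV, validating every row against the type invariants.

    Row order is preserved; a header-only file yields an empty list.

    Raises
    ------
    SchemaError
        If a required column is missing from the header.
    RowError
        If a row cannot be parsed or violates a record invariant; the error
        carries the 0-based data-row index.
    """
    columns = _columns_for(schema)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        missing = [c for c in columns if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        return [_parse_row(row, schema, i) for i, row in enumerate(reader)]


def write_metadata(records: Sequence[MetadataRecord], path: str | Path) -> Path:
    """Write records to a CSV with fixed column order.

    All records are validated before any bytes are written; an unset
    ``crop_path`` serializes as an empty cell. ``read_metadata`` of the
    written file reproduces the records field-by-field.
    """
    records = list(records)
    classified = any(isinstance(r, ClassifiedRecord) for r in records)
    if classified and not all(isinstance(r, ClassifiedRecord) for r in records):
        raise ValueError("cannot mix raw and classified records in one file")
    for rec in records:
        rec.validate()
    path = Path(path)
    columns = CLASSIFIED_COLUMNS if classified else RAW_COLUMNS
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for rec in records:
            writer.writerow(_record_to_row(rec))
    return path


def merge_metadata(paths: Sequence[str | Path]) -> list[MetadataRecord]:
    """Merge several metadata files from one camera trap's output.

    All files must share one schema (raw or classified, auto-detected).
    Records are concatenated and ordered by ``(recording_id, timestamp)``;
    identity is never collapsed across files because it is the composite
    ``(recording_id, track_id)`` key. Exact duplicate rows (same recording,
    track, timestamp and bbox) are kept but trigger a warning — at ~1 s
    capture frequency legitimate repeats always differ in timestamp.
    """
    if not paths:
        return []
    schemas = {detect_schema(p) for p in paths}
    if len(schemas) > 1:
        raise SchemaError(f"mixed schemas across files: {sorted(schemas)}")
    schema = schemas.pop()
    merged: list[MetadataRecord] = []
    for p in paths:
        merged.extend(read_metadata(p, schema))
    seen: set[tuple] = set()
    for rec in merged:
        key = (rec.recording_id, rec.track_id, rec.timestamp, rec.bbox)
        if key in seen:
            warnings.warn(
                f"exact duplicate row kept: recording {rec.recording_id!r} "
                f"track {rec.track_id} at t={rec.timestamp}",
                stacklevel=2,
            )
        seen.add(key)
    merged.sort(key=lambda r: (r.recording_id, r.timestamp))
    return merged
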