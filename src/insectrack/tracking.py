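"""Multi-object insect tracking: constant-velocity Kalman filter + Hungarian
data association on bounding-box IoU.

The on-device detector emits per-frame bounding boxes in normalized frame
coordinates. The tracker assigns a stable, strictly increasing unique ID to
each insect by predicting every live track forward under constant-velocity
dynamics, scoring track/detection pairs with ``1 - IoU`` between the
predicted and observed boxes, gating out implausible pairs, and solving the
resulting assignment problem optimally. Detections that match no live track
spawn new IDs; tracks unmatched for too many frames are terminated. The
number of unique IDs is the downstream unit of insect activity/abundance
estimation, so the tracker's failure mode of interest is *fragmentation*:
at low effective frame rates a fast, erratically flying insect moves far
between detections, the IoU gate rejects the match, the track is lost and
the same individual receives a new ("jumping") ID, inflating counts.

State vector: ``(cx, cy, w, h, vcx, vcy)`` — box center, size and center
velocity in normalized units; width/height follow static dynamics. The
measurement is ``(cx, cy, w, h)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Detection",
    "Track",
    "TrackStatus",
    "TrackerConfig",
    "InsectTracker",
    "StepResult",
    "iou",
    "bbox_to_state",
    "state_to_bbox",
    "kalman_predict",
    "kalman_update",
    "assignment_cost",
    "hungarian_solve",
]

_DIM_X = 6  # (cx, cy, w, h, vcx, vcy)
_DIM_Z = 4  # (cx, cy, w, h)

_H = np.zeros((_DIM_Z, _DIM_X))
_H[:4, :4] = np.eye(4)


@dataclass(frozen=True)
class Detection:
    """One detector output on one frame (normalized coordinates)."""

    timestamp: float
    bbox: tuple[float, float, float, float]
    confidence: float
    label: str = "insect"

    def __post_init__(self):
        x_min, y_min, x_max, y_max = self.bbox
        clipped = tuple(float(np.clip(v, 0.0, 1.0)) for v in self.bbox)
        object.__setattr__(self, "bbox", clipped)
        x_min, y_min, x_max, y_max = clipped
        if not (x_min < x_max and y_min < y_max):
            raise ValueError(f"degenerate bbox after clipping: {clipped}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


class TrackStatus(str, Enum):
    TENTATIVE = "tentative"
    ACTIVE = "active"
    LOST = "lost"
    TERMINATED = "terminated"


@dataclass
class Track:
    """A tracked individual: filter state, lifecycle status, history."""

    track_id: int
    state: np.ndarray  # shape (6,)
    covariance: np.ndarray  # shape (6, 6)
    status: TrackStatus = TrackStatus.TENTATIVE
    frames_since_update: int = 0
    hits: int = 1
    history: list[Detection] = field(default_factory=list)
    last_timestamp: float | None = None

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """Bounding box recovered from the (possibly predicted) state."""
        return state_to_bbox(self.state)


@dataclass(frozen=True)
class TrackerConfig:
    """Tracker tuning knobs.

    ``fps`` is the effective pipeline rate: ~12.5 when synchronizing with
    1080p high-resolution frames, ~3.4 for 4K. It is informational here
    (time deltas come from detection timestamps) but determines the
    fragmentation regime the tracker operates in. Noise parameters are
    variances in normalized frame units.
    """

    iou_gate: float = 0.2
    max_lost_frames: int = 5
    min_hits: int = 1
    process_noise: float = 1e-3
    measurement_noise: float = 1e-2
    fps: float = 12.5

    def __post_init__(self):
        if not (0.0 <= self.iou_gate <= 1.0):
            raise ValueError(f"iou_gate {self.iou_gate} outside [0, 1]")
        if self.max_lost_frames < 0:
            raise ValueError("max_lost_frames must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")


# -- geometry ----------------------------------------------------------------

def iou(a: Sequence[float], b: Sequence[float]) -> float:
    """Intersection-over-union of two (x_min, y_min, x_max, y_max) boxes."""
    ix_min = max(a[0], b[0])
    iy_min = max(a[1], b[1])
    ix_max = min(a[2], b[2])
    iy_max = min(a[3], b[3])
    iw = max(0.0, ix_max - ix_min)
    ih = max(0.0, iy_max - iy_min)
    inter = iw * ih
    if inter == 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def bbox_to_state(bbox: Sequence[float]) -> np.ndarray:
    """Corner box -> (cx, cy, w, h) measurement vector."""
    x_min, y_min, x_max, y_max = bbox
    return np.array(
        [(x_min + x_max) / 2.0, (y_min + y_max) / 2.0, x_max - x_min, y_max - y_min]
    )


def state_to_bbox(state: np.ndarray) -> tuple[float, float, float, float]:
    """(cx, cy, w, h, ...) state -> corner box."""
    cx, cy, w, h = state[:4]
    return (float(cx - w / 2), float(cy - h / 2), float(cx + w / 2), float(cy + h / 2))


# -- Kalman filter -----------------------------------------------------------

def _transition(dt: float) -> np.ndarray:
    F = np.eye(_DIM_X)
    F[0, 4] = dt
    F[1, 5] = dt
    return F


def kalman_predict(track: Track, dt: float, process_noise: float = 1e-3) -> Track:
    """Advance a track by ``dt`` seconds under constant-velocity dynamics.

    The covariance grows by ``process_noise * dt`` per state dimension, so
    uncertainty accumulates with elapsed time rather than with step count.
    Returns a new Track; the input is not modified.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if not np.all(np.isfinite(track.state)):
        raise ValueError(f"non-finite track state: {track.state}")
    F = _transition(dt)
    state = F @ track.state
    cov = F @ track.covariance @ F.T + process_noise * dt * np.eye(_DIM_X)
    return replace(track, state=state, covariance=cov)


def kalman_update(track: Track, detection: Detection, measurement_noise: float = 1e-2) -> Track:
    """Fold a gated detection into a track's state (measurement update).

    The posterior mean lies between prediction and measurement, and the
    covariance trace never increases relative to the prior.
    """
    z = bbox_to_state(detection.bbox)
    R = measurement_noise * np.eye(_DIM_Z)
    S = _H @ track.covariance @ _H.T + R
    if np.linalg.cond(S) > 1e12:
        raise np.linalg.LinAlgError("singular innovation covariance")
    K = track.covariance @ _H.T @ np.linalg.inv(S)
    innovation = z - _H @ track.state
    state = track.state + K @ innovation
    cov = (np.eye(_DIM_X) - K @ _H) @ track.covariance
    history = track.history + [detection]
    return replace(
        track,
        state=state,
        covariance=cov,
        history=history,
        frames_since_update=0,
        hits=track.hits + 1,
        last_timestamp=detection.timestamp,
    )


# -- data association --------------------------------------------------------

def assignment_cost(
    tracks: Sequence[Track],
    detections: Sequence[Detection],
    iou_gate: float = 0.2,
) -> np.ndarray:
    """``1 - IoU`` cost matrix (tracks x detections) with infeasible cells.

    Pairs whose IoU between the track's predicted box and the detection box
    falls below ``iou_gate`` are marked ``inf`` (infeasible). Either side
    may be empty, yielding a degenerate matrix.
    """
    cost = np.full((len(tracks), len(detections)), np.inf)
    for i, trk in enumerate(tracks):
        pred_box = trk.bbox
        for j, det in enumerate(detections):
            overlap = iou(pred_box, det.bbox)
            if overlap >= iou_gate and overlap > 0.0:
                cost[i, j] = 1.0 - overlap
    return cost


def hungarian_solve(
    cost: np.ndarray,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost assignment over the feasible (finite) cells.

    Returns ``(pairs, unmatched_rows, unmatched_cols)``. Among matchings of
    maximum feasible cardinality the total cost is minimal; ties between
    equal-cost assignments resolve deterministically to the lowest row
    index (scipy's lexicographic order).
    """
    cost = np.asarray(cost, dtype=float)
    n_rows, n_cols = cost.shape
    if n_rows == 0 or n_cols == 0 or not np.any(np.isfinite(cost)):
        return [], list(range(n_rows)), list(range(n_cols))
    # big-M stand-in keeps the LP finite while making infeasible cells
    # strictly worse than any all-feasible alternative
    big = 1e6
    padded = np.where(np.isfinite(cost), cost, big)
    rows, cols = linear_sum_assignment(padded)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols) if np.isfinite(cost[r, c])]
    matched_rows = {r for r, _ in pairs}
    matched_cols = {c for _, c in pairs}
    unmatched_rows = [r for r in range(n_rows) if r not in matched_rows]
    unmatched_cols = [c for c in range(n_cols) if c not in matched_cols]
    return pairs, unmatched_rows, unmatched_cols


# -- tracker -----------------------------------------------------------------

@dataclass(frozen=True)
class StepResult:
    """Outcome of one tracker step."""

    matched: list[tuple[int, Detection]]  # (track_id, detection)
    new_tracks: list[tuple[int, Detection]]  # (track_id, spawning detection)
    terminated_track_ids: list[int]

    @property
    def new_track_ids(self) -> list[int]:
        return [tid for tid, _ in self.new_tracks]


class InsectTracker:
    """Stateful frame-by-frame tracker.

    Feed each frame's detections in timestamp order through :meth:`step`.
    Track IDs start at 1, increase strictly at creation and are never
    reused. New tracks start tentative and are promoted to active after
    ``min_hits`` matches (with the default ``min_hits=1`` a track is active
    from its first detection, mirroring a pipeline that saves an image crop
    immediately). Active tracks that miss a frame become lost but stay
    matchable; a lost track re-activates on a successful match or is
    terminated after ``max_lost_frames`` consecutive misses.
    """

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self._next_id = 1
        self._tracks: dict[int, Track] = {}
        self._last_timestamp: float | None = None

    @property
    def live_tracks(self) -> list[Track]:
        """Tracks still eligible for matching (not terminated)."""
        return [t for t in self._tracks.values() if t.status != TrackStatus.TERMINATED]

    @property
    def ids_created(self) -> int:
        return self._next_id - 1

    def _new_track(self, detection: Detection) -> Track:
        state = np.zeros(_DIM_X)
        state[:4] = bbox_to_state(detection.bbox)
        cov = np.eye(_DIM_X)
        cov[4:, 4:] *= 10.0  # velocity unobserved at birth
        cov *= self.config.measurement_noise
        status = (
            TrackStatus.ACTIVE if self.config.min_hits <= 1 else TrackStatus.TENTATIVE
        )
        track = Track(
            track_id=self._next_id,
            state=state,
            covariance=cov,
            status=status,
            history=[detection],
            last_timestamp=detection.timestamp,
        )
        self._next_id += 1
        self._tracks[track.track_id] = track
        return track

    def step(self, detections: Sequence[Detection], timestamp: float) -> StepResult:
        """Process one frame: predict, associate, update, spawn, terminate."""
        if self._last_timestamp is not None and timestamp <= self._last_timestamp:
            raise ValueError(
                f"non-monotone timestamp {timestamp} (previous {self._last_timestamp})"
            )
        cfg = self.config
        live = self.live_tracks
        if self._last_timestamp is not None:
            dt = timestamp - self._last_timestamp
            for trk in live:
                self._tracks[trk.track_id] = kalman_predict(trk, dt, cfg.process_noise)
            live = self.live_tracks
        self._last_timestamp = timestamp

        cost = assignment_cost(live, detections, cfg.iou_gate)
        pairs, unmatched_rows, unmatched_cols = hungarian_solve(cost)

        matched: list[tuple[int, Detection]] = []
        for row, col in pairs:
            trk = live[row]
            updated = kalman_update(trk, detections[col], cfg.measurement_noise)
            updated.status = (
                TrackStatus.ACTIVE if updated.hits >= cfg.min_hits else TrackStatus.TENTATIVE
            )
            self._tracks[trk.track_id] = updated
            matched.append((trk.track_id, detections[col]))

        terminated: list[int] = []
        for row in unmatched_rows:
            trk = live[row]
            trk.frames_since_update += 1
            if trk.status == TrackStatus.TENTATIVE:
                trk.status = TrackStatus.TERMINATED
                terminated.append(trk.track_id)
            elif trk.frames_since_update > cfg.max_lost_frames:
                trk.status = TrackStatus.TERMINATED
                terminated.append(trk.track_id)
            else:
                trk.status = TrackStatus.LOST

        new_tracks = [
            (self._new_track(detections[col]).track_id, detections[col])
            for col in unmatched_cols
        ]
        return StepResult(matched=matched, new_tracks=new_tracks, terminated_track_ids=terminated)
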