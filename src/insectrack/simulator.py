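"""Synthetic hoverfly motion and detection-stream simulator.

Emulates the lab tracking-accuracy experiment: a handful of hoverflies
(Episyrphus balteatus, a fast erratic flyer) released over a platform that
fills the camera frame, recorded for a fixed interval at the pipeline's
effective frame rate. Each insect alternates between three motion modes —
sitting (near-stationary), walking (slow smooth random walk) and darting
(fast flight with abrupt direction changes) — and occasionally leaves the
frame and re-enters later, which counts as a new *visit*. Ground truth is
the per-insect trajectory plus the total number of visits, the quantity a
human observer counts from reference video.

Detections are rendered from the truth at frame times spaced ``1/fps``:
each present insect is seen with probability ``1 - miss_prob``, its box is
perturbed by Gaussian coordinate jitter and its confidence drawn from a
clipped normal. Darting between two consecutive frames at a low frame rate
moves an insect further than its own box size, so the tracker's IoU gate
rejects the association and the track fragments — the "jumping ID" regime
the experiment quantifies.

Trajectories are integrated on a fine internal time grid (25 Hz) so the
same physical scenario can be sampled at any pipeline frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .frame_geometry import CaptureThrottle
from .metadata_io import ClassifiedRecord, NULL_CLASS
from .postprocess import PostprocessConfig, filter_tracks, summarize
from .tracking import Detection, InsectTracker, TrackerConfig

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "InsectTrajectory",
    "generate_scenario",
    "render_detections",
    "stream_to_csv",
    "stream_from_csv",
    "track_stream",
    "run_tracking_experiment",
]

_FINE_DT = 0.04  # internal trajectory integration step, seconds (25 Hz)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one simulated recording interval.

    Defaults replicate the lab experiment's shape: 15 hoverflies over a
    frame-filling platform, a 900 s recording, and the slow 4K-synchronized
    pipeline rate of ~3.4 fps. Speeds are fractions of the frame width per
    second; default dart speeds lie in the band that ~12.5 fps sampling can
    still associate across frames but ~3.4 fps cannot — faster flights
    leave the frame entirely and are modelled as exits (``dart_exit_prob``).
    """

    n_insects: int = 15
    duration: float = 900.0
    fps: float = 3.4
    mode_probs: dict = field(
        default_factory=lambda: {"sit": 0.57, "walk": 0.37, "dart": 0.06}
    )
    mode_speed: dict = field(
        default_factory=lambda: {
            "sit": (0.0, 0.003),
            "walk": (0.01, 0.04),
            "dart": (0.08, 0.20),
        }
    )
    mode_dwell_s: dict = field(
        default_factory=lambda: {"sit": 5.0, "walk": 2.5, "dart": 0.6}
    )
    exit_reentry_rate: float = 0.2  # spontaneous frame exits per insect per minute
    dart_exit_prob: float = 0.8  # chance a dart ends with the insect leaving the frame
    reentry_delay_s: float = 6.0  # mean absence before re-entry
    bbox_size_range: tuple[float, float] = (0.035, 0.055)  # box side, frame fraction
    miss_prob: float = 0.05
    jitter_sd: float = 0.004
    confidence_mean: float = 0.75
    confidence_sd: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_insects < 0:
            raise ValueError("n_insects must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        probs = self.mode_probs
        if set(probs) != {"sit", "walk", "dart"}:
            raise ValueError("mode_probs must have keys sit, walk, dart")
        if any(not 0 <= p <= 1 for p in probs.values()):
            raise ValueError("mode_probs values must lie in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("mode_probs must sum to 1")
        if not (0.0 <= self.miss_prob <= 1.0):
            raise ValueError("miss_prob must lie in [0, 1]")
        if not (0.0 <= self.dart_exit_prob <= 1.0):
            raise ValueError("dart_exit_prob must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.exit_reentry_rate < 0:
            raise ValueError("exit_reentry_rate must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario field(s): {sorted(unknown)}")
        for key in ("bbox_size_range",):
            if key in data:
                data[key] = tuple(data[key])
        if "mode_speed" in data:
            data["mode_speed"] = {k: tuple(v) for k, v in data["mode_speed"].items()}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class InsectTrajectory:
    """One insect's ground truth on the fine time grid."""

    times: np.ndarray  # fine grid, shared across insects
    present: np.ndarray  # bool mask
    cx: np.ndarray  # NaN while absent
    cy: np.ndarray
    width: float
    height: float

    @property
    def presence_intervals(self) -> list[tuple[float, float]]:
        """Disjoint (start, end) intervals of presence in the arena."""
        mask = self.present
        edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
        starts = [0] if mask[0] else []
        starts += [int(e) + 1 for e in edges if not mask[e]]
        ends = [int(e) for e in edges if mask[e]]
        if mask[-1]:
            ends.append(len(mask) - 1)
        return [(float(self.times[s]), float(self.times[e])) for s, e in zip(starts, ends)]


@dataclass
class GroundTruth:
    """All trajectories plus the manually-countable number of frame visits."""

    config: ScenarioConfig
    trajectories: list[InsectTrajectory]
    true_visits: int


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (triangle-wave folding)."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    return lo + np.where(y > span, 2 * span - y, y)


def _simulate_insect(
    rng: np.random.Generator, cfg: ScenarioConfig, times: np.ndarray
) -> tuple[InsectTrajectory, int]:
    """Timeline of mode-switching segments with exits coupled to flight.

    A hoverfly leaves the frame predominantly by darting off the platform
    (each dart ends in an exit with probability ``dart_exit_prob``); a
    small spontaneous exit hazard (``exit_reentry_rate``) covers take-offs
    from rest. Absences are exponential and re-entry lands the insect at a
    fresh random position — one new frame visit.
    """
    n = len(times)
    w = rng.uniform(*cfg.bbox_size_range)
    h = rng.uniform(*cfg.bbox_size_range)
    lo_x, hi_x = w / 2, 1 - w / 2
    lo_y, hi_y = h / 2, 1 - h / 2

    present = np.ones(n, dtype=bool)
    cx = np.full(n, np.nan)
    cy = np.full(n, np.nan)
    modes = list(cfg.mode_probs)
    probs = np.array([cfg.mode_probs[m] for m in modes])
    spont_rate = cfg.exit_reentry_rate / 60.0

    pos = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
    i = 0
    while i < n:
        mode = modes[rng.choice(len(modes), p=probs)]
        dwell = max(_FINE_DT, rng.exponential(cfg.mode_dwell_s[mode]))
        n_steps = min(n - i, max(1, int(round(dwell / _FINE_DT))))
        speed = rng.uniform(*cfg.mode_speed[mode])
        theta0 = rng.uniform(0, 2 * np.pi)
        if mode == "walk":
            theta = theta0 + np.cumsum(rng.normal(0, 0.4, n_steps))
        elif mode == "dart":
            theta = theta0 + np.cumsum(rng.normal(0, 0.7, n_steps))
        else:
            theta = np.full(n_steps, theta0)
        seg_x = _fold(pos[0] + np.cumsum(speed * np.cos(theta)) * _FINE_DT, lo_x, hi_x)
        seg_y = _fold(pos[1] + np.cumsum(speed * np.sin(theta)) * _FINE_DT, lo_y, hi_y)
        cx[i : i + n_steps] = seg_x
        cy[i : i + n_steps] = seg_y
        pos = np.array([seg_x[-1], seg_y[-1]])
        i += n_steps
        if i >= n:
            break
        exits = (mode == "dart" and rng.random() < cfg.dart_exit_prob) or (
            rng.random() < 1.0 - np.exp(-spont_rate * n_steps * _FINE_DT)
        )
        if exits:
            away = rng.exponential(cfg.reentry_delay_s)
            n_away = max(1, int(round(away / _FINE_DT)))
            j = min(n, i + n_away)
            present[i:j] = False
            i = j
            pos = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])

    cx[~present] = np.nan
    cy[~present] = np.nan
    traj = InsectTrajectory(
        times=times, present=present, cx=cx, cy=cy, width=w, height=h
    )
    return traj, len(traj.presence_intervals)


def generate_scenario(config: ScenarioConfig) -> GroundTruth:
    """Generate ground-truth trajectories; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.duration, _FINE_DT)
    trajectories: list[InsectTrajectory] = []
    true_visits = 0
    for _ in range(config.n_insects):
        traj, visits = _simulate_insect(rng, config, times)
        trajectories.append(traj)
        true_visits += visits
    return GroundTruth(config=config, trajectories=trajectories, true_visits=true_visits)


def render_detections(
    truth: GroundTruth,
    config: ScenarioConfig | None = None,
    seed: int | None = None,
) -> list[tuple[float, list[Detection]]]:
    """Sample a noisy detection stream from the truth at frame times.

    Frames are spaced ``1/fps``; each present insect is detected with
    probability ``1 - miss_prob``, with Gaussian bbox jitter (clipped to
    the arena) and a clipped-normal confidence. The detection RNG is
    separate from the trajectory RNG (seeded from ``seed`` or the
    scenario's seed + 1) so the same physical truth can be re-rendered.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    frame_times = np.arange(0.0, config.duration, 1.0 / config.fps)
    fine_times = truth.trajectories[0].times if truth.trajectories else np.array([])
    stream: list[tuple[float, list[Detection]]] = []
    for t in frame_times:
        idx = int(round(t / _FINE_DT))
        dets: list[Detection] = []
        for traj in truth.trajectories:
            i = min(idx, len(fine_times) - 1)
            if not traj.present[i]:
                continue
            if rng.random() < config.miss_prob:
                continue
            cx, cy = traj.cx[i], traj.cy[i]
            bbox = np.array(
                [
                    cx - traj.width / 2,
                    cy - traj.height / 2,
                    cx + traj.width / 2,
                    cy + traj.height / 2,
                ]
            )
            if config.jitter_sd > 0:
                bbox = bbox + rng.normal(0, config.jitter_sd, 4)
            bbox = np.clip(bbox, 0.0, 1.0)
            if bbox[0] >= bbox[2] or bbox[1] >= bbox[3]:
                continue  # jitter collapsed the box at the arena edge
            conf = float(np.clip(rng.normal(config.confidence_mean, config.confidence_sd), 0.05, 1.0))
            dets.append(
                Detection(timestamp=float(t), bbox=tuple(bbox), confidence=conf)
            )
        stream.append((float(t), dets))
    return stream


# -- stream CSV interchange --------------------------------------------------

_STREAM_COLUMNS = ["timestamp", "label", "confidence", "x_min", "y_min", "x_max", "y_max"]


def stream_to_csv(stream: Sequence[tuple[float, Sequence[Detection]]], path: str | Path) -> Path:
    """Export a detection stream (pre-tracking, so no track IDs) to CSV."""
    rows = [
        {
            "timestamp": t,
            "label": d.label,
            "confidence": d.confidence,
            "x_min": d.bbox[0],
            "y_min": d.bbox[1],
            "x_max": d.bbox[2],
            "y_max": d.bbox[3],
        }
        for t, dets in stream
        for d in dets
    ]
    df = pd.DataFrame(rows, columns=_STREAM_COLUMNS)
    path = Path(path)
    # shortest-repr floats so a read-back stream is bit-identical
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return path


def stream_from_csv(path: str | Path) -> list[tuple[float, list[Detection]]]:
    """Read a detection stream CSV back into per-frame groups."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing stream column(s) {missing}")
    stream: list[tuple[float, list[Detection]]] = []
    for t, group in df.groupby("timestamp", sort=True):
        dets = [
            Detection(
                timestamp=float(t),
                bbox=(row.x_min, row.y_min, row.x_max, row.y_max),
                confidence=float(row.confidence),
                label=str(row.label),
            )
            for row in group.itertuples()
        ]
        stream.append((float(t), dets))
    return stream


# -- pipeline composition ----------------------------------------------------

Classifier = Callable[[Detection], tuple[tuple[str, str, str], tuple[float, float, float]]]


def _echo_classifier(det: Detection):
    """Default stand-in classifier: echo the detector label as top-1."""
    return (det.label, NULL_CLASS, NULL_CLASS), (det.confidence, 0.0, 0.0)


def track_stream(
    stream: Sequence[tuple[float, Sequence[Detection]]],
    tracker_config: TrackerConfig | None = None,
    capture_frequency: float = 1.0,
    recording_id: str = "rec0",
    classifier: Classifier | None = None,
    time_origin: float = 0.0,
) -> tuple[list[ClassifiedRecord], int]:
    """Run the tracker over a stream and emit throttled metadata records.

    Mirrors the on-device pipeline: every matched or newly created track
    may save one cropped image per ``capture_frequency`` seconds; each
    saved image becomes one classified metadata row (classification itself
    is pluggable and defaults to echoing the detector label). Returns the
    records and the total number of tracking IDs ever created.
    """
    tracker = InsectTracker(tracker_config)
    throttle = CaptureThrottle(capture_frequency)
    classify = classifier or _echo_classifier
    records: list[ClassifiedRecord] = []
    for t, dets in stream:
        result = tracker.step(list(dets), t)
        for track_id, det in result.matched + result.new_tracks:
            if not throttle.should_capture(track_id, t):
                continue
            classes, probs = classify(det)
            records.append(
                ClassifiedRecord(
                    recording_id=recording_id,
                    timestamp=time_origin + det.timestamp,
                    track_id=track_id,
                    label=det.label,
                    confidence=det.confidence,
                    bbox=det.bbox,
                    top_classes=classes,
                    top_probs=probs,
                )
            )
    return records, tracker.ids_created


def run_tracking_experiment(
    config: ScenarioConfig,
    tracker_config: TrackerConfig | None = None,
    min_tracks_values: Sequence[int] = tuple(range(1, 11)),
    capture_frequency: float = 1.0,
    postprocess_config: PostprocessConfig | None = None,
) -> pd.DataFrame:
    """Replicate the tracking-accuracy experiment for one scenario seed.

    Runs the full pipeline — generate truth, render detections, track,
    throttle captures, summarize — then filters the per-track summaries at
    each minimum-images setting. Returns a table with one row per setting:
    ``min_tracks``, ``estimated_ids`` (kept tracks), ``unfiltered_ids``
    (tracks before filtering), and ``true_visits``.
    """
    tracker_config = tracker_config or TrackerConfig(fps=config.fps)
    truth = generate_scenario(config)
    stream = render_detections(truth)
    records, _ = track_stream(
        stream, tracker_config, capture_frequency, recording_id=f"sim-{config.seed}"
    )
    base = postprocess_config or PostprocessConfig()
    report = summarize(records, base)
    all_summaries = []  # rebuild the unfiltered summary set for re-filtering
    wide_cfg = PostprocessConfig(
        min_images=1,
        max_images=10**9,
        dedup_window=base.dedup_window,
        dedup_threshold=base.dedup_threshold,
        platform_size_mm=base.platform_size_mm,
        non_insect_classes=base.non_insect_classes,
    )
    all_summaries = summarize(records, wide_cfg).kept
    rows = []
    for m in min_tracks_values:
        cfg_m = PostprocessConfig(
            min_images=m,
            max_images=base.max_images,
            dedup_window=base.dedup_window,
            dedup_threshold=base.dedup_threshold,
            platform_size_mm=base.platform_size_mm,
            non_insect_classes=base.non_insect_classes,
        )
        kept, _, _ = filter_tracks(all_summaries, cfg_m)
        rows.append(
            {
                "min_tracks": int(m),
                "estimated_ids": len(kept),
                "unfiltered_ids": len(all_summaries),
                "true_visits": truth.true_visits,
            }
        )
    return pd.DataFrame(rows)
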