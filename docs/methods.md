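# Methods

This note documents the models and procedures implemented in `insectrack`,
the parameter defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical and design choices
made where the problem left room.

## Tracking model

The tracker is a minimal SORT-style realization of "Kalman filter +
Hungarian algorithm" tracking-by-detection.

**State and dynamics.** Each track carries
`x = (cx, cy, w, h, vcx, vcy)`: box center, box size, and center velocity,
all in normalized frame coordinates (the detector's 320×320 input is a
stretched downscale of the high-resolution frame, so normalized
coordinates are shared by both streams). Dynamics are constant-velocity
for the center and static for the size:

```
F(dt) = I6 with F[0,4] = F[1,5] = dt        (center advected by velocity)
H     = [I4 | 0]                            (box observed, velocity not)
Q     = q · dt · I6,   R = r · I4
```

Process noise grows with elapsed time rather than step count, so the
filter behaves consistently across pipeline frame rates. The measurement
update uses the standard gain `K = P Hᵀ (H P Hᵀ + R)⁻¹`; an innovation
covariance with condition number above 1e12 raises an error rather than
silently producing garbage.

**Association.** The cost of matching track *i* to detection *j* is
`1 − IoU(predicted box_i, observed box_j)`; pairs with IoU below
`iou_gate` are infeasible. The assignment is solved exactly
(`scipy.optimize.linear_sum_assignment` on the finite cells, with a large
constant standing in for infeasible ones; assignments landing on an
infeasible cell are discarded afterwards). Ties between equal-cost
assignments resolve to the lowest track index, deterministically.

**Lifecycle.** New tracks start `tentative` and are promoted to `active`
after `min_hits` matches. The default `min_hits = 1` activates a track on
its first detection, because the emulated pipeline saves an image crop
immediately — every detection is evidence worth keeping at ~1 s capture
frequency. An active track that misses a frame becomes `lost` but remains
matchable; it *re-activates* if matched within `max_lost_frames` frames
and terminates otherwise. Allowing lost → active is deliberate: keeping
lost tracks matchable is the entire purpose of the lost state, and
without re-activation a single missed detection would fragment every
track. Tentative tracks that miss terminate immediately. IDs increase
strictly at creation and are never reused.

**Defaults** (all configurable): `iou_gate = 0.2`, `max_lost_frames = 5`,
`min_hits = 1`, `process_noise = 1e-3`, `measurement_noise = 1e-2`
(variances in normalized units). The original on-device tracker's gating
and noise parameters are not published; these values produce stable
single-ID tracking of slow insects at ~12.5 fps and the documented
fragmentation regime at ~3.4 fps, which is the behavior the package needs
to reproduce faithfully.

## Frame geometry

Pixel rectangles are 0-based and half-open, `[x_min, x_max) × [y_min,
y_max)`, with floor rounding on minima and ceil on maxima so box-edge
insect pixels are never cut off. Normalized coordinates are clipped to
the frame before rounding; a box that collapses to zero area raises a
degenerate-box error. Capture throttling is per track: each tracking ID
saves at most one crop per `frequency` seconds (default 1.0 s),
independent of how many insects are present. No padding or aspect
preservation is applied to crops — the rectangle is exactly the scaled
bounding box.

## Post-processing

One output row per `(recording_id, track_id)` — tracking IDs are only
unique within a recording interval, so identity is always this composite
key and is never collapsed across merged files.

- **Final class**: argmax of the weighted mean classification probability
  `mean(top-1 prob of class c) × n_images(c) / n_images(track)`. Exact
  ties break to the lexicographically smallest class and set an explicit
  tie flag.
- **Image-count filter**: keep iff `min_images ≤ n ≤ max_images`
  (defaults 3 and 1800). The boundaries are inclusive: a track with
  exactly 3 images is kept ("fewer than three are excluded").
- **Size**: the track's *mean* bounding box (jitter-robust, rather than
  any single record's box) scaled by the physical platform dimensions in
  millimeters.
- **Re-entry flagging**: per kept track, the minimum of
  `start_time − previous.end_time` over the up to 5 most recent earlier
  tracks of the same final class; gaps under 5 s set a flag. The gap is
  measured end-to-start (re-entry latency); measuring start-to-start
  would be a one-line change in `dedup_gap`. Flagged tracks are reported,
  not removed — whether they are true duplicates cannot be decided from
  metadata alone.
- **Activity**: `n_ids × 60 / minutes`, reported half-up to an integer
  (61.5 → 62) with the exact value retained.
- The four non-insect classes (`none_bg`, `none_bird`, `none_dirt`,
  `none_shadow`) stay in the output but are excluded from activity counts
  and the flagged-share denominator.

## Synthetic data generator

The generator emulates the structure of a lab tracking-accuracy
experiment: `n_insects` hoverflies over a platform that fills the unit
frame, recorded for `duration` seconds and sampled at the pipeline rate
`fps`. Per insect:

- **Motion** is a mode-switching random walk integrated on a fine 25 Hz
  grid (so one physical scenario can be sampled at any frame rate):
  *sit* (speed ≤ 0.003 frame-widths/s, fixed heading), *walk* (0.01–0.04,
  meandering heading), *dart* (0.08–0.20, strongly diffusing heading).
  Dwell times are exponential (means 5.0 / 2.5 / 0.6 s), mode choice
  i.i.d. with probabilities 0.57 / 0.37 / 0.06. Positions reflect at the
  arena boundary.
- **Exits** happen two ways: each dart ends with the insect leaving the
  frame with probability `dart_exit_prob = 0.8` (fast flight off the
  platform), plus a small spontaneous exit hazard of 0.2 events/min.
  Absences are exponential (mean 6 s); re-entry teleports the insect to a
  fresh random position and counts as a new **visit** — the ground-truth
  unit a human observer tallies from reference video.
- **Detection noise**: per frame each present insect is seen with
  probability `1 − miss_prob` (default miss 0.05), box coordinates get
  Gaussian jitter (sd 0.004, clipped to the arena), confidence is a
  clipped normal (0.75 ± 0.10). The detection RNG is separate from the
  trajectory RNG so one truth can be re-rendered.

**Why the dart band is 0.08–0.20 frame-widths/s.** With equal boxes of
side `w`, the IoU gate of 0.2 tolerates an inter-frame displacement of
roughly `0.6 w`. With the default box sizes (0.035–0.055) this means
~3.4 fps sampling loses any motion faster than ~0.09 frame-widths/s while
~12.5 fps sampling can follow up to ~0.3. The default dart band sits in
exactly this window, which is the regime that produces the documented
effect: fragmentation ("jumping IDs") at the 4K-synchronized rate and
stable tracking at the 1080p rate. Genuinely fast flight (a hoverfly can
cross the platform in well under a second) is not modelled as trackable
in-frame motion at all — it leaves the frame, which is what
`dart_exit_prob` represents. Configuring dart speeds far above the band
makes motion untrackable at *every* rate, and then the number of
fragments simply scales with the sampling rate — more IDs at 12.5 fps
than at 3.4 — inverting the effect the instrument actually shows.

**Default scenario** (the lab replica): 15 insects, 900 s, 3.4 fps, ten
`min_tracks` settings 1–10. One run produces a few hundred true visits
and a few-fold unfiltered overestimate, matching the qualitative pattern
of the original experiment (no numeric table of it exists to match more
than qualitatively).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: appearance (no images are synthesized, so
classification is a pluggable stand-in that echoes the detector label);
insects approaching each other closely (real ID switches from proximity
are not reproduced); detector failure modes that correlate over time
(misses are i.i.d.); platform-edge occlusion; diurnal/weather activity
structure. Conclusions about *tracking geometry and bookkeeping* transfer;
conclusions about detector or classifier accuracy do not.

## Numerical choices

- Timestamps are rounded to milliseconds on record construction and
  serialized as ISO-8601 UTC with millisecond precision, making CSV
  round-trips byte-exact while preserving sub-second ordering at 12.5 fps.
- Floats in CSVs are written in shortest-`repr` form and parsed with
  pandas' round-trip parser where bit-exactness matters.
- The assignment solver's brute-force test oracle enumerates permutations
  of the larger side (≤ 6! = 720 per matrix), keeping exhaustive
  verification cheap.
- Half-up integer rounding for reported activity (`floor(x + 0.5)`), not
  banker's rounding: 61.5 reports as 62.
- Degenerate inputs fail loudly: empty track record sets, non-finite
  states, zero-area boxes, non-monotone frame timestamps and singular
  innovation covariances all raise typed errors.

## Problem sizes in tests and acceptance runs

The test suite and `scripts/acceptance.py` run the lab-replica experiment
at its full size (15 insects, 900 s, 3.4 fps) over 10 seeds, the
fps-comparison property at a reduced 8-insect / 60–120 s size over 20
paired seeds, and the assignment oracle on 1,000 random matrices up to
6×6. These sizes keep a full run in the minutes range on one CPU while
leaving every qualitative effect comfortably outside seed noise.

## Known limitations

- The tracker is appearance-free; two insects crossing paths can swap
  IDs, and nothing re-identifies an individual after a long absence.
- The original software's CSV column names are not published; this
  package's schema is a faithful reconstruction of the listed fields, not
  byte-compatible with the original files.
- The original tracking-accuracy experiment can only be matched
  qualitatively: the on-device tracker's gating and noise parameters, and
  the experiment's numeric results table, are unpublished.
- `merge_metadata` assumes recording IDs are globally unique identifiers
  of recording intervals (true for timestamp-derived IDs).
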