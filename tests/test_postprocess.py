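"""Per-track classification aggregation, filtering, dedup gaps, activity."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from insectrack.metadata_io import ClassifiedRecord, NULL_CLASS
from insectrack.postprocess import (
    PostprocessConfig,
    TrackSummary,
    activity_rate,
    assign_top1,
    bbox_size_mm,
    dedup_gap,
    filter_tracks,
    summarize,
    weighted_class_probabilities,
)


def rec(track_id=1, t=0.0, cls="A", prob=0.9, recording="rec1", bbox=(0.1, 0.1, 0.2, 0.2)):
    return ClassifiedRecord(
        recording_id=recording,
        timestamp=1690000000.0 + t,
        track_id=track_id,
        label="insect",
        confidence=0.9,
        bbox=bbox,
        top_classes=(cls, NULL_CLASS, NULL_CLASS),
        top_probs=(prob, 0.0, 0.0),
    )


def summary(track_id=1, cls="hfly_episyr", n_images=5, start=0.0, end=10.0, prob=0.8):
    return TrackSummary(
        recording_id="rec1",
        track_id=track_id,
        top1_class=cls,
        top1_weighted_prob=prob,
        n_images=n_images,
        start_time=start,
        end_time=end,
        width_mm=10.0,
        height_mm=10.0,
    )


WORKED_TRACK = [
    rec(t=0, cls="A", prob=0.9),
    rec(t=1, cls="A", prob=0.8),
    rec(t=2, cls="A", prob=0.7),
    rec(t=3, cls="B", prob=0.6),
]


class TestWeightedProbabilities:
    def test_worked_example(self):
        """3 images of A at (0.9, 0.8, 0.7) + 1 of B at 0.6:
        A scores mean(0.8) * 3/4 = 0.6, B scores 0.6 * 1/4 = 0.15."""
        scores = weighted_class_probabilities(WORKED_TRACK)
        assert scores["A"] == pytest.approx(0.6)
        assert scores["B"] == pytest.approx(0.15)

    def test_single_class_collapses_to_plain_mean(self):
        records = [rec(t=i, cls="C", prob=0.85) for i in range(5)]
        assert weighted_class_probabilities(records)["C"] == pytest.approx(0.85)

    def test_single_record(self):
        assert weighted_class_probabilities([rec(cls="D", prob=0.9)])["D"] == pytest.approx(0.9)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            weighted_class_probabilities([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        labels=st.lists(st.sampled_from("ABC"), min_size=1, max_size=12),
        probs=st.data(),
    )
    def test_weighted_score_bounded_by_share_and_mean(self, labels, probs):
        """Each class score <= its image share and <= its plain mean prob;
        shares themselves sum to 1 over occurring classes."""
        records = [
            rec(t=i, cls=c, prob=probs.draw(st.floats(0.01, 1.0)))
            for i, c in enumerate(labels)
        ]
        scores = weighted_class_probabilities(records)
        n = len(records)
        share_total = 0.0
        for cls, score in scores.items():
            cls_recs = [r for r in records if r.top1_class == cls]
            share = len(cls_recs) / n
            mean_prob = sum(r.top1_prob for r in cls_recs) / len(cls_recs)
            share_total += share
            assert score <= share + 1e-12
            assert score <= mean_prob + 1e-12
        assert share_total == pytest.approx(1.0)


class TestAssignTop1:
    def test_worked_example_argmax(self):
        cls, prob, tie = assign_top1(WORKED_TRACK)
        assert (cls, prob, tie) == ("A", pytest.approx(0.6), False)

    def test_uniform_track(self):
        cls, prob, tie = assign_top1([rec(t=i, cls="C", prob=0.7) for i in range(3)])
        assert cls == "C" and not tie

    def test_exact_tie_breaks_lexicographically_with_flag(self):
        records = [
            rec(t=0, cls="B", prob=0.8),
            rec(t=1, cls="B", prob=0.8),
            rec(t=2, cls="A", prob=0.8),
            rec(t=3, cls="A", prob=0.8),
        ]
        cls, prob, tie = assign_top1(records)
        assert cls == "A" and prob == pytest.approx(0.4) and tie


class TestFilterTracks:
    @pytest.mark.parametrize(
        "n_images,bucket",
        [(2, "below"), (3, "kept"), (1800, "kept"), (1801, "above")],
    )
    def test_boundaries(self, n_images, bucket):
        kept, below, above = filter_tracks([summary(n_images=n_images)], PostprocessConfig())
        got = "kept" if kept else ("below" if below else "above")
        assert got == bucket

    def test_partition_is_exact(self):
        summaries = [summary(track_id=i, n_images=n) for i, n in enumerate([1, 2, 3, 100, 1800, 1801, 5000], 1)]
        kept, below, above = filter_tracks(summaries, PostprocessConfig())
        assert len(kept) + len(below) + len(above) == len(summaries)
        assert [s.n_images for s in below] == [1, 2]
        assert [s.n_images for s in above] == [1801, 5000]

    def test_kept_count_monotone_in_thresholds(self):
        summaries = [summary(track_id=i, n_images=i) for i in range(1, 40)]
        kept_counts = [
            len(filter_tracks(summaries, PostprocessConfig(min_images=m))[0])
            for m in range(1, 10)
        ]
        assert kept_counts == sorted(kept_counts, reverse=True)


class TestBboxSizeMm:
    def test_direct_scaling(self):
        w, h = bbox_size_mm((0.2, 0.1, 0.3, 0.3), (350.0, 200.0))
        assert w == pytest.approx(35.0)
        assert h == pytest.approx(40.0)

    def test_full_frame_is_platform(self):
        assert bbox_size_mm((0, 0, 1, 1), (500.0, 280.0)) == pytest.approx((500.0, 280.0))

    def test_degenerate_zero_width(self):
        w, _ = bbox_size_mm((0.5, 0.1, 0.5, 0.3), (350.0, 200.0))
        assert w == 0.0


class TestDedupGap:
    def test_first_of_class_undefined_and_unflagged(self):
        out, n = dedup_gap([summary()], PostprocessConfig())
        assert out[0].prev_same_class_gap_s is None
        assert not out[0].dedup_flag and n == 0

    def test_three_second_gap_flagged_at_default_threshold(self):
        first = summary(track_id=1, start=0.0, end=10.0)
        second = summary(track_id=2, start=13.0, end=20.0)
        out, n = dedup_gap([first, second], PostprocessConfig())
        assert out[1].prev_same_class_gap_s == pytest.approx(3.0)
        assert out[1].dedup_flag and n == 1

    def test_gap_measured_to_nearest_previous_end(self):
        tracks = [
            summary(track_id=1, start=0.0, end=5.0),
            summary(track_id=2, start=10.0, end=30.0),
            summary(track_id=3, start=40.0, end=41.0),
        ]
        out, _ = dedup_gap(tracks, PostprocessConfig())
        assert out[2].prev_same_class_gap_s == pytest.approx(10.0)  # vs end=30, not end=5

    def test_window_limits_lookback(self):
        # seven prior same-class tracks; only the most recent five inspected
        prior = [summary(track_id=i, start=10.0 * i, end=10.0 * i + 1) for i in range(7)]
        target = summary(track_id=99, start=200.0, end=201.0)
        out, _ = dedup_gap(prior + [target], PostprocessConfig(dedup_window=5))
        # gap vs track_id 2..6 ends (21..61): min = 200 - 61 = 139
        assert out[-1].prev_same_class_gap_s == pytest.approx(139.0)

    def test_different_classes_do_not_interact(self):
        a = summary(track_id=1, cls="bee", start=0.0, end=10.0)
        b = summary(track_id=2, cls="fly", start=11.0, end=20.0)
        out, n = dedup_gap([a, b], PostprocessConfig())
        assert out[1].prev_same_class_gap_s is None and n == 0


class TestActivityRate:
    def test_worked_extrapolation(self):
        """41 unique IDs in a 40 min interval -> 61.5/h, reported 62."""
        rate = activity_rate(41, 40)
        assert rate.exact == pytest.approx(61.5)
        assert rate.reported == 62

    def test_zero_ids(self):
        assert activity_rate(0, 123.0).exact == 0.0

    def test_identity_duration(self):
        assert activity_rate(10, 60).reported == 10

    def test_half_up_rounding(self):
        assert activity_rate(1, 40).reported == 2  # 1.5 rounds up, not to even

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            activity_rate(5, 0)


class TestSummarize:
    def test_worked_track_composition(self):
        report = summarize(WORKED_TRACK, PostprocessConfig())
        assert report.n_total == 1 and report.n_kept == 1
        s = report.kept[0]
        assert s.top1_class == "A"
        assert s.top1_weighted_prob == pytest.approx(0.6)
        assert s.n_images == 4
        assert s.duration_s == pytest.approx(3.0)

    def test_short_track_counted_below(self):
        records = [rec(track_id=5, t=i) for i in range(2)]
        report = summarize(records, PostprocessConfig())
        assert report.n_kept == 0 and report.n_removed_below == 1

    def test_mean_bbox_converted_to_mm(self):
        records = [
            rec(t=0, bbox=(0.1, 0.1, 0.2, 0.2)),
            rec(t=1, bbox=(0.1, 0.1, 0.3, 0.4)),
            rec(t=2, bbox=(0.1, 0.1, 0.2, 0.2)),
        ]
        cfg = PostprocessConfig(platform_size_mm=(300.0, 150.0))
        s = summarize(records, cfg).kept[0]
        # mean width fraction (0.1 + 0.2 + 0.1)/3, mean height (0.1 + 0.3 + 0.1)/3
        assert s.width_mm == pytest.approx(300.0 * 0.4 / 3)
        assert s.height_mm == pytest.approx(150.0 * 0.5 / 3)

    def test_row_order_invariance(self):
        records = WORKED_TRACK + [rec(track_id=2, t=i, cls="C", prob=0.5) for i in range(4)]
        fwd = summarize(records, PostprocessConfig())
        rev = summarize(records[::-1], PostprocessConfig())
        assert [dataclasses.astuple(s) for s in fwd.kept] == [
            dataclasses.astuple(s) for s in rev.kept
        ]

    def test_non_insect_classes_kept_but_not_counted(self):
        insect = [rec(track_id=1, t=i, cls="bee") for i in range(3)]
        shadow = [rec(track_id=2, t=i + 0.5, cls="none_shadow") for i in range(3)]
        report = summarize(insect + shadow, PostprocessConfig())
        assert report.n_kept == 2
        assert report.n_insect_kept == 1

    def test_flagged_share_over_insect_tracks(self):
        # two bee tracks 2 s apart -> second flagged; one shadow track ignored
        records = (
            [rec(track_id=1, t=i, cls="bee") for i in range(3)]
            + [rec(track_id=2, t=4 + i, cls="bee") for i in range(3)]
            + [rec(track_id=3, t=10 + i, cls="none_bg") for i in range(3)]
        )
        report = summarize(records, PostprocessConfig())
        assert report.n_flagged == 1
        assert report.flagged_share_pct == pytest.approx(50.0)

    def test_raw_records_rejected(self):
        from insectrack.metadata_io import MetadataRecord

        raw = MetadataRecord("r", 0.0, 1, "insect", 0.9, (0.1, 0.1, 0.2, 0.2))
        with pytest.raises(TypeError):
            summarize([raw], PostprocessConfig())


def test_config_invariants():
    with pytest.raises(ValueError):
        PostprocessConfig(min_images=5, max_images=4)
    with pytest.raises(ValueError):
        PostprocessConfig(dedup_window=0)
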