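"""Per-track classification aggregation and activity extrapolation.

A tracked insect photographed four times gets classified per image: three
images say class A (probabilities 0.9, 0.8, 0.7) and one says class B
(0.6). The weighted mean classification probability scores each class by
its mean probability times its share of the track's images; the argmax is
the track's final class. The script also extrapolates 41 unique IDs seen
in a 40 min recording interval to an hourly activity value.
"""

from insectrack import ClassifiedRecord, activity_rate, assign_top1, weighted_class_probabilities
from insectrack.metadata_io import NULL_CLASS

track = [
    ClassifiedRecord(
        recording_id="rec1",
        timestamp=float(i),
        track_id=1,
        label="insect",
        confidence=0.9,
        bbox=(0.10, 0.10, 0.20, 0.20),
        top_classes=(cls, NULL_CLASS, NULL_CLASS),
        top_probs=(prob, 0.0, 0.0),
    )
    for i, (cls, prob) in enumerate([("A", 0.9), ("A", 0.8), ("A", 0.7), ("B", 0.6)])
]

scores = weighted_class_probabilities(track)
top_class, top_score, tie = assign_top1(track)
print("weighted mean classification probabilities per class:")
for cls, score in sorted(scores.items()):
    print(f"  {cls}: {score:.4g}")
print(f"track classified as {top_class!r} with weighted probability {top_score:.2f}")
print()

rate = activity_rate(n_ids=41, recording_minutes=40)
print(f"41 unique IDs in 40 min -> {rate.exact} IDs/h, reported as {rate.reported}")
print("(the per-hour value is the study's activity/abundance proxy)")
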