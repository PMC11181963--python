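"""Average precision under the two score-tie dialects.

Three detections, two of them sharing confidence 0.80, against two
reference objects: the AP depends on whether tied predictions are
swept one at a time or as one block.
"""

from valimet import APConfig, BoundingBox, Instance, InstanceSet, MatchConfig, average_precision

refs = [InstanceSet("img", [
    Instance(box=BoundingBox((0, 0), (2, 2))),
    Instance(box=BoundingBox((10, 10), (12, 12))),
])]
preds = [InstanceSet("img", [
    Instance(box=BoundingBox((0, 0), (2, 2)), confidence=0.9),     # hit
    Instance(box=BoundingBox((10, 10), (12, 12)), confidence=0.8),  # hit, tied score
    Instance(box=BoundingBox((20, 20), (22, 22)), confidence=0.8),  # miss, tied score
])]

match = MatchConfig(criterion="box_iou", threshold=0.5)
for dialect in ("per_prediction", "grouped_by_score"):
    ap = average_precision(preds, refs, match, APConfig(tie_dialect=dialect))
    print(f"AP[{dialect:18s}] = {ap.value:.4f}   flags={ap.flags}")

print()
print("Same detections, same matching criterion — different AP, purely")
print("because the implementations disagree on how equal scores enter the")
print("precision-recall sweep. Always report the dialect with the number.")
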