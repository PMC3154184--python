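"""Score a single drawing: raw error counts -> standard scores -> indices.

The subject below drew four distorted lines, got one right angle wrong and
rotated the cube; everything else was error-free, and the vigilance task
(Random Letter Test) was clean.
"""

from scct import SubjectRawRecord, standardize_record

raw = SubjectRawRecord(
    subject_id="demo-01",
    raw={
        "SCCT-1": 0,   # missing lines
        "SCCT-2": 0,   # lines not parallel
        "SCCT-3": 4,   # distorted lines
        "SCCT-4": 0,   # missing angles
        "SCCT-5": 1,   # right angles which are not
        "SCCT-6": 0,   # angles with different size
        "SCCT-7": 0,   # missing elements
        "SCCT-8": 0,   # distorted elements
        "SCCT-9": 0,   # elements 1 and 2
        "SCCT-10": 0,  # elements 3-6
        "SCCT-11": 0,  # three-dimensional level missing
        "SCCT-12": "Yes",  # rotation
        "SCCT-13": "No",   # mirror image
        "SCCT-14": "No",   # closing-in
        "RLT-A": 0,    # vigilance omissions
        "RLT-B": 1,    # vigilance intrusions
    },
)

record = standardize_record(raw)
print("item standard scores:")
for item_id, score in record.item_scores.items():
    print(f"  {item_id:8s} {score:6.0f}")
print("subscales:", record.subscales)
print("indices:  ", record.indices)
print(f"SCCT total: {record.scct_total:.0f} / 1400")
print(f"RLT: omissions {record.rlt_a:.0f}, intrusions {record.rlt_b:.0f}")
# Each standard score is (roughly) the percentage of healthy controls
# performing that badly or worse: 40 on distorted lines means 40% of the
# normative sample drew 4+ distorted lines, while Rotation at 20 is rare
# (about one control in five rotated the cube).  The total of 1210 sits a
# little below the healthy-control mean total (~1080-1130).
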