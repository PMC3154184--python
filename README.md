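# scct — Standardized Copy of the Cube Test scoring engine

Copying a Necker cube (a wireframe cube in isometric perspective) is a
classic paper-and-pencil probe of visuoconstructive ability, but coarse 0–2
ratings lose almost all of the information in a psychiatric patient's
drawing.  The SCCT scores a cube copy on 14 detailed error items — missing
or non-parallel lines, distorted angles, missing elements, rotation, mirror
imaging, closing-in — plus two vigilance items from the Random Letter Test
(RLT), and norms each item against a healthy-control sample.

This package is the complete scoring engine for researchers and clinicians
using the instrument, plus the machinery needed to validate it without
access to raw study data:

* **Norming.**  Each raw observation maps to a **standard score** `S ∈
  [0, 100]`: for raw category `r`, `S(r)` is the cumulative percentage of
  the normative sample (n = 93) performing at `r` *or worse*, rounded
  half-up, with error-free performance pinned at `S(0) = 100`.  The
  published norm table ships as versioned package data; the same percentile
  rule can re-derive a table from any normative cohort CSV.
* **Aggregation.**  Item scores sum into five subscales — Missing Elements
  `ME = S₁+S₄+S₇+S₁₁`, Deformation `D = S₂+S₃+S₅+S₆+S₈+S₉+S₁₀`, Mirror
  Image `M = S₁₃`, Rotation `R = S₁₂`, Close-In `CI = S₁₄` — and three
  indices: Deficit `DcI = ME + M`, Deformation `DfI = D + R`, Closing-In
  `CiI = CI`.  The SCCT total is the plain sum of the 14 item scores
  (max 1400); RLT scores are reported alongside but excluded.
* **Classification.**  Two published discriminant rules assign control vs
  patient: the simplified inequality `2·S₄ + 3·S₅ + 2·S₁₃ ≥ 363.6 ⇒
  control`, and a pair of group-specific linear functions (larger value
  wins).  Coefficients are applied as published, never refit.
* **Reliability.**  Cronbach's α with alpha-if-item-deleted (zero-variance
  items dropped, as the instrument's own analysis did), per-item inter-rater
  Pearson R, and Bland-Altman-style (average, difference) agreement pairs.
* **Synthetic cohorts.**  A seeded generator samples raw records from the
  normative frequencies; a one-parameter severity mixture per item is
  calibrated so simulated patients match the published patient means,
  making every downstream module testable end to end.

## Worked example

```python
from scct import SubjectRawRecord, standardize_record
from scct.classify import classify_simplified

raw = SubjectRawRecord("demo-01", raw={
    "SCCT-1": 0, "SCCT-2": 0, "SCCT-3": 4, "SCCT-4": 0, "SCCT-5": 1,
    "SCCT-6": 0, "SCCT-7": 0, "SCCT-8": 0, "SCCT-9": 0, "SCCT-10": 0,
    "SCCT-11": 0, "SCCT-12": "Yes", "SCCT-13": "No", "SCCT-14": "No",
    "RLT-A": 0, "RLT-B": 1,
})
rec = standardize_record(raw)
print(rec.subscales)   # {'ME': 400.0, 'D': 590.0, 'M': 100.0, 'R': 20.0, 'CI': 100.0}
print(rec.indices)     # {'DcI': 500.0, 'DfI': 610.0, 'CiI': 100.0}
print(rec.scct_total)  # 1210.0
print(classify_simplified(rec).assigned)  # 'control'
```

Four distorted lines score 40 (40% of healthy controls drew four or more),
one wrong right angle scores 50, and the rotated cube scores 20 (about one
control in five rotates).  The total of 1210 sits a little below the
healthy-control mean total (~1080–1130); the discriminant value
2·100 + 3·50 + 2·100 = 550 ≥ 363.6 keeps the subject on the control side.

The `examples/` directory holds short narrative scripts for each
capability (scoring, norm derivation, classification, reliability), and the
same operations are available from a shell:

```
scct score --input subjects.csv --out scored.csv
scct norms derive --input cohort.csv --out norms.json
scct norms compare --tolerance 3
scct classify --input subjects.csv --rule simplified --out classified.csv
scct simulate --n-controls 93 --n-patients 127 --seed 1 --out cohort.csv
scct alpha --input scored.csv
scct reliability --ratings-a a.csv --ratings-b b.csv --out report.json
```

## Layout

```
src/scct/
  instrument.py   item definitions, packaged norm table, validation
  norms.py        frequency tabulation, percentile derivation, comparison
  scoring.py      standardization, subscales/indices, RLT, cohort summaries
  classify.py     published discriminant rules, confusion metrics
  reliability.py  Cronbach's alpha, inter-rater agreement
  synthetic.py    seeded cohort simulation and severity calibration
  reference.py    published group-level score profiles
  io.py, cli.py   subject CSV schema, reports, command-line surface
```

See `docs/methods.md` for the scoring model, its assumptions, and known
limitations (including one documented inconsistency between the published
discriminant rule and the published classification table).
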