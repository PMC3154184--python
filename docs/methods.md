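# Methods

## The scoring model

The instrument converts raw drawing errors into percentile-anchored
standard scores.  For an item with ordered raw categories `r = 0, 1, …`
(best to worst; for the three judgement items, No before Yes), the standard
score is

    S(0) = 100
    S(r) = round_half_up( 100 · #{subjects scoring r or worse} / n )   for r > 0

over a normative cohort of healthy controls (n = 93 in the shipped table).
`S` is monotone non-increasing by construction, bounded in [0, 100], and
invariant under duplicating the cohort.  Two idiosyncrasies of the shipped
table are preserved verbatim rather than regenerated:

* the published column was additionally hand-rounded, mostly to multiples
  of 5 in its upper range, with no single consistent rounding rule (63.44
  printed as 65 but 52.69 as 50).  The derivation above reproduces every
  published cell within ±3; the package scores subjects with the published
  values and uses the reproducible rule only for user-derived tables;
* raw categories never observed in the cohort inherit the cumulative
  percentage at that point (visible in the shipped table itself), and the
  closing-in item — never observed in any control — assigns 0 to "Yes",
  consistent with the percentile logic.

Catch-all raw rows (">2", "1–10", …) are right-open bins; counts at or
beyond a terminal bin clamp into it with a logged notice.

Aggregation is purely additive: subscales ME (items 1, 4, 7, 11),
D (2, 3, 5, 6, 8, 9, 10), M (13), R (12), CI (14); indices DcI = ME + M,
DfI = D + R, CiI = CI; total = sum of all 14 item scores (RLT excluded —
the published item means of the younger control stratum sum to within 5
points of the printed total mean only without the RLT rows).  Missing items
are a hard error by default; an explicit prorating flag scales the total by
14/(items rated) and flags the record, never silently.

Age-stratified summaries split at 40 years with the boundary in the younger
stratum, matching the published "below 41"/"above 40" headers.

## Classification

Both published rules use items 4, 5 and 13.  The simplified inequality
reads "≥ 363.6 ⇒ control" (the printed operator taken literally; boundary
cases are measure-zero in practice).  The full rule evaluates both
group-specific linear functions and assigns the larger; exact ties go to
patient (conservative toward flagging pathology, logged).  The two rules'
implied hyperplanes differ slightly; both are exposed and no reconciliation
is attempted.  Confusion percentages are truncated, not rounded, to two
decimals — the convention of the published classification table, whose
control rate 62.36 equals 58/93 truncated.

A documented inconsistency: the published confusion matrix (62.36% of
controls, 89.76% of patients correct) cannot be produced by the published
simplified rule applied to data matching the published group profiles.  Any
subject with perfect missing-angles and mirror-image scores reaches at
least 2·100 + 2·100 = 400 ≥ 363.6 and is assigned control; that covers
~96% of subjects drawn from the control norm table but also the majority of
patients matching the published patient item means (S₄ = 71.83,
S₁₃ = 85.37), capping the patient-correct rate near 45% under *any* joint
distribution with those means.  The corresponding end-to-end acceptance
check applies the stated conditions and fails; it is retained as
documentation of the discrepancy rather than weakened.

## Reliability

α uses the standard `k/(k−1)·(1 − Σ item variances / total variance)` with
n−1 variances; zero-variance items are dropped with a warning (reported as
absent, never 0 or 1 — matching how the instrument's own item analysis
excluded the invariant closing-in item), and alpha-if-deleted is reported
when more than two usable items remain.  Inter-rater output pairs Pearson R
(association) with per-subject (average, difference) tuples and difference
summaries (agreement); the two originals are exactly recoverable as
average ∓ difference/2.  Pearson R rather than ICC or kappa is the primary
coefficient for fidelity to the instrument's validation analysis; the pair
output enables Bland-Altman-style inspection without prescribing a plot.

## Synthetic cohorts

The generator's control condition samples each item's raw category from the
normative frequency table, so the expected standardized mean of every item
equals its frequency-weighted standard score exactly (closed form, asserted
in tests) — e.g. Rotation (74·100 + 19·20)/93 = 83.66.  Patients use a
per-item two-component mixture: with probability λ the worst raw category,
otherwise a control draw.  The expected mean is linear and decreasing in λ,
so a monotone bisection calibrates λ per item to any attainable target mean
(the published patient means are the default targets; two of them —
elements-1-and-2 at 79.89 and rotation at 84.76 — exceed the control
expectation and are reported as unattainable with λ = 0, about 1–2 points
short).  Ranged raw bins contribute their lower edge as the representative
raw value.

Items are independent by default; the "coupled" mode reuses one uniform
severity draw per subject across all items' mixture indicators, inducing
positive inter-item correlation — the simplest mechanism qualitatively
matching the instrument's positive inter-item correlations, with nothing
finer identifiable from printed summaries.  What the simulator does *not*
emulate: the published patient SDs, the full inter-item correlation matrix,
factor loadings, or any age structure; passing tests therefore demonstrate
correctness of the scoring pipeline and calibration machinery, not realism
of patient response profiles.

All sampling flows from a single integer seed through one `numpy`
Generator; identical configurations reproduce cohorts record for record.

## Problem sizes and numerical choices

Deterministic checks run at the instrument's own scale (93-subject
normative reconstructions, ~92 norm-table cells).  Stochastic checks use
10⁴ subjects for law-of-large-numbers anchors (±2 points on a mean whose
per-subject SD is ~32) and 1.5–2·10³ per group for ordering/correlation
properties; calibration bisection runs 60 iterations (λ resolved to ~10⁻¹⁸,
far below the 5-point acceptance band on achieved means).  Rounding of
derived standard scores is half-up (floor(x + 0.5)); report percentages are
truncated to 2 decimals as above; all other arithmetic is double precision.

## Known limitations

* The published Deformation Index group means (e.g. 182.60 for younger
  controls) are inconsistent with DfI = D + R computed from the same
  table's subscale means (536.10) and with every simple rescaling; the
  additive definition is kept for symmetry with DcI, which reproduces its
  printed means exactly, and DfI values from this package are accordingly
  on the additive scale, not the published one.
* The published α = 0.75 and the per-item inter-rater coefficients require
  the study's subject-level and double-rated data, which were never
  released; the reliability module is validated by algebraic properties and
  an independent-oracle cross-check instead.
* Norms are unstratified (a single table; no age or sex adjustment), as
  published.  Derivation from cohorts below n = 50 warns about percentile
  instability.
* No attempt is made to rate drawings automatically; scoring starts from
  human-rated raw counts.
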