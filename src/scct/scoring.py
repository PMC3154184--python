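"""Standardize raw records and aggregate them into subscales, indices and totals.

A subject's raw observations (error counts and Yes/No judgements on the 14
drawing items, plus Random Letter Test omissions/intrusions) are converted to
0-100 standard scores by table lookup and then summed:

* subscales — ME = items 1+4+7+11 (0-400), D = items 2+3+5+6+8+9+10 (0-700),
  M = item 13, R = item 12, CI = item 14;
* indices — DcI = ME + M, DfI = D + R, CiI = CI;
* the SCCT total is the plain sum of the 14 item scores (max 1400).

RLT scores are reported alongside but enter neither the subscales nor the
total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .instrument import InstrumentSpec, RawValue, canonical_instrument

logger = logging.getLogger(__name__)

GROUPS = ("control", "patient", "unknown")

#: The four printed Random Letter Test sequences, read aloud by the examiner.
RANDOM_LETTER_SERIES: tuple[str, ...] = (
    "LTPEAOAISTDALAA",
    "ANIABFSAMPZEOAD",
    "PAKLATSXTOEABAA",
    "ZYFMTSAHEOAAPAT",
)


@dataclass
class SubjectRawRecord:
    """One subject's raw observations across the instrument's items."""

    subject_id: str
    raw: dict[str, RawValue]
    group: str = "unknown"
    age: float | None = None
    rater_id: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.subject_id}: unknown group {self.group!r}")


@dataclass
class StandardizedRecord:
    """Per-item standard scores with subscale, index and total aggregates."""

    subject_id: str
    item_scores: dict[str, float]
    subscales: dict[str, float]
    indices: dict[str, float]
    scct_total: float
    rlt_a: float | None = None
    rlt_b: float | None = None
    group: str = "unknown"
    age: float | None = None
    rater_id: str | None = None
    prorated: bool = False


@dataclass(frozen=True)
class LetterSeries:
    """A letter sequence of the vigilance task and its target letter."""

    sequence: str
    target: str = "A"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty letter series")
        if not self.sequence.isalpha():
            raise ValueError(f"letter series must be letters only: {self.sequence!r}")
        if len(self.target) != 1 or not self.target.isalpha():
            raise ValueError(f"target must be a single letter: {self.target!r}")


def count_target_letters(series: LetterSeries | str, target: str = "A") -> int:
    """Number of target-letter occurrences in a vigilance series."""
    if isinstance(series, str):
        series = LetterSeries(series, target)
    return series.sequence.upper().count(series.target.upper())


def score_rlt(
    omissions: int,
    intrusions: int,
    norms: InstrumentSpec | None = None,
) -> tuple[int, int]:
    """Standard scores for the Random Letter Test error counts."""
    norms = norms or canonical_instrument()
    if omissions < 0 or intrusions < 0:
        raise ValueError("RLT error counts must be non-negative")
    return norms.lookup("RLT-A", omissions), norms.lookup("RLT-B", intrusions)


def standardize_record(
    raw: SubjectRawRecord,
    norms: InstrumentSpec | None = None,
    *,
    prorate_missing: bool = False,
) -> StandardizedRecord:
    """Score one subject: per-item lookups, then subscales, indices and total.

    All 14 drawing items must be present; RLT items are optional.  With
    ``prorate_missing`` the total is scaled by 14/(items rated) instead of
    failing, and the record is flagged — subscales then cover rated items
    only.  Prorating is never silent.
    """
    norms = norms or canonical_instrument()
    item_scores: dict[str, float] = {}
    missing: list[str] = []
    for item_id in norms.scct_item_ids:
        value = raw.raw.get(item_id)
        if value is None:
            missing.append(item_id)
        else:
            item_scores[item_id] = float(norms.lookup(item_id, value))
    unknown = set(raw.raw) - set(norms.item_ids)
    if unknown:
        raise KeyError(f"{raw.subject_id}: unknown item ids {sorted(unknown)}")
    if missing and not prorate_missing:
        raise ValueError(
            f"{raw.subject_id}: missing items {missing} "
            "(pass prorate_missing=True to prorate the total)"
        )
    if missing:
        logger.warning(
            "%s: prorating total over %d of 14 items (missing %s)",
            raw.subject_id, len(item_scores), missing,
        )

    subscales = {
        sub: float(sum(item_scores.get(m, 0.0) for m in members if m in item_scores))
        for sub, members in norms.subscales.items()
    }
    indices = {
        idx: float(sum(subscales[s] for s in members))
        for idx, members in norms.indices.items()
    }
    total = float(sum(item_scores.values()))
    n_scct = len(norms.scct_item_ids)
    if missing:
        total *= n_scct / len(item_scores)

    rlt_a = rlt_b = None
    if "RLT-A" in raw.raw and raw.raw["RLT-A"] is not None:
        rlt_a = float(norms.lookup("RLT-A", raw.raw["RLT-A"]))
    if "RLT-B" in raw.raw and raw.raw["RLT-B"] is not None:
        rlt_b = float(norms.lookup("RLT-B", raw.raw["RLT-B"]))

    return StandardizedRecord(
        subject_id=raw.subject_id,
        item_scores=item_scores,
        subscales=subscales,
        indices=indices,
        scct_total=total,
        rlt_a=rlt_a,
        rlt_b=rlt_b,
        group=raw.group,
        age=raw.age,
        rater_id=raw.rater_id,
        prorated=bool(missing),
    )


def standardize_cohort(
    cohort: Iterable[SubjectRawRecord],
    norms: InstrumentSpec | None = None,
    **kwargs,
) -> list[StandardizedRecord]:
    norms = norms or canonical_instrument()
    return [standardize_record(r, norms, **kwargs) for r in cohort]


def _record_row(rec: StandardizedRecord) -> dict[str, float]:
    row: dict[str, float] = dict(rec.item_scores)
    row.update(rec.subscales)
    row.update(rec.indices)
    row["SCCT"] = rec.scct_total
    if rec.rlt_a is not None:
        row["RLT-A"] = rec.rlt_a
    if rec.rlt_b is not None:
        row["RLT-B"] = rec.rlt_b
    return row


#: Age-stratum labels; the boundary age belongs to the younger stratum.
YOUNG, OLD = "<=40", ">40"


def cohort_summary(
    records: Sequence[StandardizedRecord],
    split_age: float | None = None,
) -> pd.DataFrame:
    """Per-group means and SDs for items, subscales, indices and totals.

    Returns a DataFrame indexed by measure with a (group[, stratum], stat)
    column MultiIndex; stats are ``mean``, ``sd`` (sample SD, n-1) and ``n``.
    With ``split_age`` each group is further split into the "<=40" and ">40"
    strata (boundary in the younger one); records without an age are dropped
    from a stratified summary.  Empty groups are simply absent.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    rows, keys = [], []
    for rec in records:
        if split_age is not None:
            if rec.age is None:
                continue
            stratum = YOUNG if rec.age <= split_age else OLD
            keys.append((rec.group, stratum))
        else:
            keys.append((rec.group,))
        rows.append(_record_row(rec))
    if not rows:
        raise ValueError("no records with an age; cannot stratify")
    frame = pd.DataFrame(rows)
    key_names = ["group", "stratum"] if split_age is not None else ["group"]
    frame.index = pd.MultiIndex.from_tuples(keys, names=key_names)

    grouped = frame.groupby(level=key_names)
    out = pd.concat(
        {"mean": grouped.mean(), "sd": grouped.std(ddof=1), "n": grouped.count()},
        names=["stat"],
    ).T  # measures x (stat, group[, stratum])
    out = out.reorder_levels(key_names + ["stat"], axis=1)
    return out.sort_index(axis=1)
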