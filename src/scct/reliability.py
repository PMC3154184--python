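"""Reliability toolkit: internal consistency and inter-rater agreement.

Cronbach's α = k/(k−1) · (1 − Σ item variances / total-score variance), with
sample (n−1) variances, plus the usual alpha-if-item-deleted column.  Items
with zero variance carry no information about consistency and are dropped
(with a warning) before computation — an instrument item on which every
subject scores identically, such as a closing-in item never observed in a
cohort, would otherwise distort the coefficient.

Inter-rater agreement follows a two-pronged design: per-item (and total-score)
Pearson correlations between the two raters, and per-subject
(average, difference) pairs with summary statistics of the differences.
Correlation alone is an index of association, not agreement — two raters
offset by a constant correlate perfectly — so the difference-vs-average pairs
(Bland-Altman style) are emitted alongside for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class RatingsMatrix:
    """Subjects x items numeric scores from a single rater (no missing cells)."""

    scores: pd.DataFrame
    rater_id: str = "rater"

    def __post_init__(self) -> None:
        self.scores = pd.DataFrame(self.scores).astype(float)
        if self.scores.isna().any().any():
            bad = self.scores.columns[self.scores.isna().any()].tolist()
            raise ValueError(
                f"{self.rater_id}: missing cells in items {bad}; "
                "listwise-complete ratings are required"
            )

    @property
    def items(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.scores)


@dataclass
class AlphaResult:
    alpha: float
    alpha_if_deleted: dict[str, float]
    dropped_items: list[str]
    n_subjects: int
    n_items: int


def _alpha_value(frame: pd.DataFrame) -> float:
    k = frame.shape[1]
    item_var = frame.var(axis=0, ddof=1).sum()
    total_var = frame.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - item_var / total_var)


def cronbach_alpha(m: RatingsMatrix | pd.DataFrame) -> AlphaResult:
    """Cronbach's α with alpha-if-item-deleted, dropping zero-variance items."""
    frame = m.scores if isinstance(m, RatingsMatrix) else pd.DataFrame(m).astype(float)
    if len(frame) < 3:
        raise ValueError(f"need at least 3 subjects, got {len(frame)}")
    variances = frame.var(axis=0, ddof=1)
    dropped = variances.index[variances == 0].tolist()
    if dropped:
        logger.warning("dropping zero-variance items from alpha: %s", dropped)
        frame = frame.drop(columns=dropped)
    if frame.shape[1] < 2:
        raise ValueError(
            f"need at least 2 items with nonzero variance, have {frame.shape[1]}"
        )
    alpha = _alpha_value(frame)
    if_deleted = {}
    if frame.shape[1] > 2:
        for col in frame.columns:
            if_deleted[col] = _alpha_value(frame.drop(columns=[col]))
    return AlphaResult(
        alpha=float(alpha),
        alpha_if_deleted={k: float(v) for k, v in if_deleted.items()},
        dropped_items=dropped,
        n_subjects=len(frame),
        n_items=frame.shape[1],
    )


@dataclass
class AgreementReport:
    """Inter-rater agreement between two raters over the same subjects and items.

    ``item_r`` omits items whose scores have zero variance under either rater
    (the correlation is undefined there, reported as absent rather than 0 or
    1).  ``pairs`` maps each item to per-subject (average, difference) tuples
    with difference = rater2 − rater1; the original ratings are recoverable as
    average ∓ difference/2.
    """

    item_r: dict[str, float]
    undefined_items: list[str]
    total_r: float | None
    diff_mean: dict[str, float]
    diff_sd: dict[str, float]
    pairs: dict[str, list[tuple[float, float]]]
    n_subjects: int
    rater_ids: tuple[str, str]

    def to_dict(self) -> dict:
        return {
            "rater_ids": list(self.rater_ids),
            "n_subjects": self.n_subjects,
            "item_r": self.item_r,
            "undefined_items": self.undefined_items,
            "total_r": self.total_r,
            "diff_mean": self.diff_mean,
            "diff_sd": self.diff_sd,
            "pairs": {k: [list(p) for p in v] for k, v in self.pairs.items()},
        }


def interrater(r1: RatingsMatrix, r2: RatingsMatrix) -> AgreementReport:
    """Per-item Pearson R, total-score R, and difference-vs-average pairs."""
    a, b = r1.scores, r2.scores
    if list(a.columns) != list(b.columns):
        raise ValueError(f"item mismatch: {list(a.columns)} vs {list(b.columns)}")
    if list(a.index) != list(b.index):
        raise ValueError("subject mismatch between raters")
    if len(a) < 2:
        raise ValueError("need at least 2 subjects")

    item_r: dict[str, float] = {}
    undefined: list[str] = []
    diff_mean: dict[str, float] = {}
    diff_sd: dict[str, float] = {}
    pairs: dict[str, list[tuple[float, float]]] = {}
    for col in a.columns:
        x, y = a[col].to_numpy(), b[col].to_numpy()
        diff = y - x
        avg = (x + y) / 2.0
        pairs[col] = list(zip(avg.tolist(), diff.tolist()))
        diff_mean[col] = float(diff.mean())
        diff_sd[col] = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
        if x.std() == 0 or y.std() == 0:
            undefined.append(col)
        else:
            item_r[col] = float(stats.pearsonr(x, y).statistic)

    ta, tb = a.sum(axis=1).to_numpy(), b.sum(axis=1).to_numpy()
    total_r = (
        float(stats.pearsonr(ta, tb).statistic)
        if ta.std() > 0 and tb.std() > 0
        else None
    )
    return AgreementReport(
        item_r=item_r,
        undefined_items=undefined,
        total_r=total_r,
        diff_mean=diff_mean,
        diff_sd=diff_sd,
        pairs=pairs,
        n_subjects=len(a),
        rater_ids=(r1.rater_id, r2.rater_id),
    )
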