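"""Discriminant classification of standardized records into control vs patient.

Two published rules, both built on the standard scores of items 4 (missing
angles), 5 (right angles which are not) and 13 (mirror image):

* the *simplified* rule, a single linear combination with a cut-off —
  ``2*S4 + 3*S5 + 2*S13 >= 363.6`` assigns healthy control;
* the *full* rule, a pair of group-specific linear discriminant functions —
  the subject is assigned to the group whose function value is larger.

Coefficients are published constants and are applied, never refit.  The two
rules are not algebraically equivalent; both are exposed and the simplified
one is the headline default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

from .scoring import StandardizedRecord

logger = logging.getLogger(__name__)

REQUIRED_ITEMS = ("SCCT-4", "SCCT-5", "SCCT-13")


def _trunc2(x: float) -> float:
    """Truncate a percentage to 2 decimals (guarding float representation)."""
    import math

    return math.floor(x * 100.0 + 1e-9) / 100.0


@dataclass(frozen=True)
class DiscriminantModel:
    """The published discriminant coefficients (immutable constants).

    ``control_coeffs``/``patient_coeffs`` are (constant, w4, w5, w13) for the
    paired group functions; ``simplified_weights`` and
    ``simplified_threshold`` define the single-inequality rule.
    """

    control_coeffs: tuple[float, float, float, float] = (-40.8311, 0.0034, 0.0058, 0.1766)
    patient_coeffs: tuple[float, float, float, float] = (-37.1956, -0.0189, -0.0194, 0.1615)
    simplified_weights: tuple[float, float, float] = (2.0, 3.0, 2.0)
    simplified_threshold: float = 363.6


PUBLISHED_MODEL = DiscriminantModel()


@dataclass
class ClassificationResult:
    subject_id: str
    rule: str  # "full" | "simplified"
    scores: dict[str, float]
    assigned: str  # "control" | "patient"


ScoreSource = Union[StandardizedRecord, Mapping[str, float]]


def _required_scores(record: ScoreSource) -> tuple[str, tuple[float, float, float]]:
    if isinstance(record, StandardizedRecord):
        subject_id, scores = record.subject_id, record.item_scores
    else:
        subject_id, scores = str(record.get("subject_id", "?")), record
    try:
        return subject_id, tuple(float(scores[i]) for i in REQUIRED_ITEMS)  # type: ignore[return-value]
    except KeyError as exc:
        raise ValueError(f"{subject_id}: item {exc.args[0]} not scored") from None


def classify_simplified(
    record: ScoreSource,
    model: DiscriminantModel = PUBLISHED_MODEL,
) -> ClassificationResult:
    """Apply the single-inequality rule; the boundary value assigns control."""
    subject_id, (s4, s5, s13) = _required_scores(record)
    w4, w5, w13 = model.simplified_weights
    value = w4 * s4 + w5 * s5 + w13 * s13
    assigned = "control" if value >= model.simplified_threshold else "patient"
    return ClassificationResult(
        subject_id=subject_id,
        rule="simplified",
        scores={"discriminant": value, "threshold": model.simplified_threshold},
        assigned=assigned,
    )


def classify_full(
    record: ScoreSource,
    model: DiscriminantModel = PUBLISHED_MODEL,
) -> ClassificationResult:
    """Apply the paired group functions; exact ties assign patient (and log)."""
    subject_id, (s4, s5, s13) = _required_scores(record)
    c0, c4, c5, c13 = model.control_coeffs
    p0, p4, p5, p13 = model.patient_coeffs
    f_control = c0 + c4 * s4 + c5 * s5 + c13 * s13
    f_patient = p0 + p4 * s4 + p5 * s5 + p13 * s13
    if f_control == f_patient:
        logger.info("%s: discriminant tie (%.4f); assigning patient", subject_id, f_control)
    assigned = "control" if f_control > f_patient else "patient"
    return ClassificationResult(
        subject_id=subject_id,
        rule="full",
        scores={"control_function": f_control, "patient_function": f_patient},
        assigned=assigned,
    )


def classify_cohort(
    records: Sequence[ScoreSource],
    rule: str = "simplified",
    model: DiscriminantModel = PUBLISHED_MODEL,
) -> list[ClassificationResult]:
    fn = {"simplified": classify_simplified, "full": classify_full}[rule]
    return [fn(r, model) for r in records]


@dataclass
class ConfusionSummary:
    """2x2 confusion counts (true group x assigned group) with percent-correct rates."""

    counts: dict[tuple[str, str], int]  # (truth, assigned) -> count
    labels: tuple[str, str] = ("control", "patient")

    def row_total(self, truth: str) -> int:
        return sum(self.counts[(truth, a)] for a in self.labels)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def rates(self) -> dict[str, float]:
        """Percent correct per true group and overall.

        Percentages are truncated (not rounded) to 2 decimals, the convention
        of the published classification table (58/93 is reported as 62.36).
        """
        out = {}
        for g in self.labels:
            n = self.row_total(g)
            out[g] = _trunc2(100.0 * self.counts[(g, g)] / n) if n else float("nan")
        correct = sum(self.counts[(g, g)] for g in self.labels)
        out["overall"] = _trunc2(100.0 * correct / self.total)
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [[self.counts[(t, a)] for a in self.labels] for t in self.labels],
            index=pd.Index(self.labels, name="truth"),
            columns=pd.Index(self.labels, name="assigned"),
        )


def confusion_metrics(
    truth: Sequence[str],
    assigned: Sequence[str],
    labels: tuple[str, str] = ("control", "patient"),
) -> ConfusionSummary:
    """Cross-tabulate true vs assigned group and report percent correct."""
    if len(truth) != len(assigned):
        raise ValueError(f"length mismatch: {len(truth)} truths, {len(assigned)} assignments")
    if len(truth) == 0:
        raise ValueError("empty label sequences")
    bad = (set(truth) | set(assigned)) - set(labels)
    if bad:
        raise ValueError(f"labels outside {labels}: {sorted(bad)}")
    counts = {(t, a): 0 for t in labels for a in labels}
    for t, a in zip(truth, assigned):
        counts[(t, a)] += 1
    return ConfusionSummary(counts=counts, labels=labels)
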