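"""Seeded synthetic cohorts of raw SCCT/RLT responses.

No subject-level data accompany the published instrument, so validation runs
on simulated cohorts built from what *is* printed:

* healthy controls draw each item's raw category from the normative frequency
  table itself, so at severity 0 the expected standardized mean of every item
  equals its frequency-weighted standard score exactly;
* patients use a one-parameter severity mixture per item: with probability
  λ the subject falls in the item's worst raw category, otherwise they respond
  like a control.  The expected standardized mean is then linear and
  decreasing in λ, and a per-item λ can be calibrated so the simulated group
  mean lands on any attainable published patient mean.

Items are sampled independently by default.  The "coupled" mode draws one
uniform severity variate per subject and reuses it for every item's mixture
indicator, inducing positive inter-item rank correlation — the simplest
mechanism producing the qualitative correlation pattern of real patient data,
with nothing finer identifiable from printed summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .instrument import InstrumentSpec, ItemDefinition, canonical_instrument
from .scoring import SubjectRawRecord

logger = logging.getLogger(__name__)


@dataclass
class CohortProfile:
    """Per-item raw-category sampling distribution for one group.

    ``base_probs`` holds, per item, the probability of each raw category in
    the item's bin order (best → worst); at severity 0 sampling reproduces
    these frequencies in expectation.  ``severity`` maps item → λ ∈ [0, 1],
    the weight of the worst-category point mass mixed into the base
    distribution.
    """

    group: str
    base_probs: dict[str, np.ndarray]
    severity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item_id, p in self.base_probs.items():
            p = np.asarray(p, dtype=float)
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{item_id}: invalid probability vector {p}")
            self.base_probs[item_id] = p / p.sum()
        for item_id, lam in self.severity.items():
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"{item_id}: severity {lam} outside [0, 1]")

    def lam(self, item_id: str) -> float:
        return self.severity.get(item_id, 0.0)


@dataclass
class SimulationConfig:
    """Cohort sizes, seed and coupling mode for one simulation run."""

    n_control: int
    n_patient: int
    seed: int
    severity: float = 0.5  # default uniform patient λ when no calibrated profile given
    correlation: str = "independent"  # or "coupled"

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_patient < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.correlation not in ("independent", "coupled"):
            raise ValueError(f"unknown correlation mode {self.correlation!r}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")


def control_profile(instrument: InstrumentSpec | None = None) -> CohortProfile:
    """The normative sampling profile: bin counts normalized to probabilities."""
    instrument = instrument or canonical_instrument()
    probs = {}
    for it in instrument.items:
        counts = np.array([b.count or 0 for b in it.bins], dtype=float)
        if counts.sum() <= 0:
            raise ValueError(f"{it.item_id}: no normative counts to sample from")
        probs[it.item_id] = counts / counts.sum()
    return CohortProfile(group="control", base_probs=probs)


def patient_profile(
    severity: float | Mapping[str, float] = 0.5,
    instrument: InstrumentSpec | None = None,
) -> CohortProfile:
    """A patient profile: the control distribution with a severity mixture."""
    instrument = instrument or canonical_instrument()
    base = control_profile(instrument)
    if isinstance(severity, Mapping):
        sev = dict(severity)
    else:
        sev = {i: float(severity) for i in base.base_probs}
    return CohortProfile(group="patient", base_probs=base.base_probs, severity=sev)


def expected_item_mean(
    profile: CohortProfile,
    item: ItemDefinition,
    lam: float | None = None,
) -> float:
    """Closed-form expected standardized mean of one item under the profile.

    E[S] = (1−λ)·Σ p_c·standard_c + λ·standard_worst, with the worst category
    being the item's last bin.
    """
    p = profile.base_probs[item.item_id]
    standards = np.array([b.standard for b in item.bins], dtype=float)
    if len(p) != len(standards):
        raise ValueError(f"{item.item_id}: probability/bin length mismatch")
    lam = profile.lam(item.item_id) if lam is None else lam
    base_mean = float(p @ standards)
    return (1.0 - lam) * base_mean + lam * float(standards[-1])


def _raw_value_for_bin(item: ItemDefinition, bin_index: int):
    b = item.bins[bin_index]
    if item.response_kind == "binary":
        return b.raw
    return b.lower  # representative raw value of a ranged/catch-all bin


def _sample_group(
    rng: np.random.Generator,
    n: int,
    profile: CohortProfile,
    instrument: InstrumentSpec,
    coupled: bool,
    id_prefix: str,
) -> list[SubjectRawRecord]:
    records = []
    item_list = list(instrument.items)
    for s in range(n):
        shared_u = rng.random() if coupled else None
        raw: dict = {}
        for item in item_list:
            p = profile.base_probs[item.item_id]
            lam = profile.lam(item.item_id)
            u = shared_u if coupled else rng.random()
            if u < lam:
                idx = len(item.bins) - 1
            else:
                idx = int(rng.choice(len(p), p=p))
            raw[item.item_id] = _raw_value_for_bin(item, idx)
        records.append(
            SubjectRawRecord(
                subject_id=f"{id_prefix}{s + 1:05d}",
                raw=raw,
                group=profile.group,
            )
        )
    return records


def sample_cohort(
    config: SimulationConfig,
    profiles: tuple[CohortProfile, CohortProfile] | None = None,
    instrument: InstrumentSpec | None = None,
) -> list[SubjectRawRecord]:
    """Draw a reproducible control + patient cohort of raw records.

    ``profiles`` is a (control, patient) pair; by default the control profile
    is the normative table and the patient profile applies ``config.severity``
    uniformly.  Identical configs yield identical cohorts record for record.
    """
    instrument = instrument or canonical_instrument()
    if profiles is None:
        profiles = (
            control_profile(instrument),
            patient_profile(config.severity, instrument),
        )
    ctrl_prof, pat_prof = profiles
    rng = np.random.default_rng(config.seed)
    coupled = config.correlation == "coupled"
    cohort = _sample_group(rng, config.n_control, ctrl_prof, instrument, coupled, "C")
    cohort += _sample_group(rng, config.n_patient, pat_prof, instrument, coupled, "P")
    return cohort


def normative_marginal_cohort(
    instrument: InstrumentSpec | None = None,
) -> list[SubjectRawRecord]:
    """Deterministic cohort whose per-item frequencies equal the normative counts exactly.

    Each item's raw categories are laid out over the subject slots in table
    order (ranged bins contribute their lower edge), so every per-item
    marginal reproduces the normative frequency table with no sampling noise;
    the joint distribution across items is an artifact of the layout and
    carries no meaning.  Useful for consistency checks of frequency-weighted
    expectations (e.g. cohort subscale means).
    """
    instrument = instrument or canonical_instrument()
    n = instrument.n_normative
    if n is None:
        n = sum(b.count or 0 for b in instrument.items[0].bins)
    columns: dict[str, list] = {}
    for item in instrument.items:
        values: list = []
        for i, b in enumerate(item.bins):
            if b.count:
                values.extend([_raw_value_for_bin(item, i)] * int(b.count))
        if len(values) != n:
            raise ValueError(
                f"{item.item_id}: counts sum to {len(values)}, expected {n}"
            )
        columns[item.item_id] = values
    return [
        SubjectRawRecord(
            subject_id=f"N{s + 1:05d}",
            raw={item_id: col[s] for item_id, col in columns.items()},
            group="control",
        )
        for s in range(n)
    ]


@dataclass
class CalibrationReport:
    """Outcome of fitting per-item severities to target standardized means."""

    lam: dict[str, float]
    achieved: dict[str, float]
    target: dict[str, float]
    unattainable: dict[str, str]  # item -> reason

    @property
    def max_abs_error(self) -> float:
        return max(
            (abs(self.achieved[i] - self.target[i]) for i in self.target),
            default=0.0,
        )


def calibrate_patient_profile(
    targets: Mapping[str, float],
    instrument: InstrumentSpec | None = None,
    tol: float = 0.01,
) -> tuple[CohortProfile, CalibrationReport]:
    """Find the per-item severity mixture matching target mean standard scores.

    For each item a monotone bisection over λ drives the closed-form expected
    mean onto the target.  Targets above the severity-0 mean or below the
    worst-category score are unattainable within the mixture family; they are
    clamped to the nearest endpoint and reported, never silently absorbed.
    """
    instrument = instrument or canonical_instrument()
    base = control_profile(instrument)
    lam: dict[str, float] = {}
    achieved: dict[str, float] = {}
    unattainable: dict[str, str] = {}
    for item_id, target in targets.items():
        if not 0.0 <= target <= 100.0:
            raise ValueError(f"{item_id}: target {target} outside [0, 100]")
        item = instrument.item(item_id)
        hi_mean = expected_item_mean(base, item, lam=0.0)
        lo_mean = expected_item_mean(base, item, lam=1.0)
        if target >= hi_mean:
            lam[item_id] = 0.0
            if target > hi_mean + tol:
                unattainable[item_id] = (
                    f"target {target:.2f} above severity-0 mean {hi_mean:.2f}"
                )
        elif target <= lo_mean:
            lam[item_id] = 1.0
            if target < lo_mean - tol:
                unattainable[item_id] = (
                    f"target {target:.2f} below worst-category mean {lo_mean:.2f}"
                )
        else:
            lo, hi = 0.0, 1.0  # expected mean decreases in lambda
            for _ in range(60):
                mid = (lo + hi) / 2.0
                if expected_item_mean(base, item, lam=mid) > target:
                    lo = mid
                else:
                    hi = mid
            lam[item_id] = (lo + hi) / 2.0
        achieved[item_id] = expected_item_mean(base, item, lam=lam[item_id])
    profile = CohortProfile(group="patient", base_probs=base.base_probs, severity=lam)
    report = CalibrationReport(
        lam=lam, achieved=achieved, target=dict(targets), unattainable=unattainable
    )
    if unattainable:
        logger.warning("unattainable calibration targets: %s", unattainable)
    return profile, report
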