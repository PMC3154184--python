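"""Norm derivation: from a normative cohort's raw responses to a standard-score table.

The standardization rule is percentile-based: the standard score attached to a
raw category is the percentage of the normative sample performing *that badly
or worse* (cumulative from the worst category), rounded half-up to the nearest
integer, with the error-free category pinned to 100.  Applied to the published
normative frequencies this reproduces the published standard-score column to
within ±3 everywhere (the published column was additionally hand-rounded to
multiples of 5 in its upper range, which this rule does not imitate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .instrument import (
    InstrumentSpec,
    ItemDefinition,
    NormBin,
    canonical_instrument,
)

logger = logging.getLogger(__name__)

#: Cohorts smaller than this make percentile scores unstable; derivation warns.
MIN_STABLE_COHORT = 50


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class FrequencyTable:
    """Normative response frequencies for one item, ordered best → worst."""

    item_id: str
    counts: dict[str, int]
    n_total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_total:
            raise ValueError(
                f"{self.item_id}: counts sum to {sum(self.counts.values())}, "
                f"not n_total={self.n_total}"
            )

    @property
    def percents(self) -> dict[str, float]:
        return {k: 100.0 * v / self.n_total for k, v in self.counts.items()}


@dataclass
class NormTable:
    """Derived standard-score lookups plus the frequencies they came from."""

    lookups: dict[str, dict[str, int]]  # item_id -> raw label -> standard
    frequencies: dict[str, FrequencyTable]
    n_total: int
    rounding: str = "half-up"
    version: str = "derived"

    def as_instrument(self, template: InstrumentSpec | None = None) -> InstrumentSpec:
        """Package the derived lookups as an :class:`InstrumentSpec`.

        Labels, response kinds and the subscale/index composition are taken
        from ``template`` (default: the canonical instrument) where the item
        exists there; items are limited to those present in this table.
        """
        template = template or canonical_instrument()
        items = []
        for item_id, lut in self.lookups.items():
            freq = self.frequencies[item_id]
            try:
                base = template.item(item_id)
                label, kind, raw_max = base.label, base.response_kind, base.raw_max
            except KeyError:
                label, kind, raw_max = item_id, "count", None
            items.append(
                ItemDefinition(
                    item_id=item_id,
                    label=label,
                    response_kind=kind,
                    raw_max=raw_max,
                    bins=tuple(
                        NormBin(
                            raw=raw,
                            standard=std,
                            count=freq.counts.get(raw),
                            percent=round(freq.percents.get(raw, 0.0), 2),
                        )
                        for raw, std in lut.items()
                    ),
                )
            )
        present = {it.item_id for it in items}
        subscales = {
            k: tuple(m for m in v if m in present)
            for k, v in template.subscales.items()
        }
        return InstrumentSpec(
            items=tuple(items),
            subscales={k: v for k, v in subscales.items() if v},
            indices=template.indices,
            version=self.version,
            n_normative=self.n_total,
        )


def tabulate_frequencies(
    cohort: Sequence,
    item_id: str,
    instrument: InstrumentSpec | None = None,
) -> FrequencyTable:
    """Tally one item's raw responses over a cohort of raw records.

    Count items are tabulated per observed integer value (gaps between 0 and
    the worst observed value are kept with zero counts, so derived categories
    are contiguous); binary items per No/Yes.  Every record must carry a
    ratable value for ``item_id``.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    instrument = instrument or canonical_instrument()
    item = instrument.item(item_id)

    values = []
    for rec in cohort:
        raw = rec.raw.get(item_id) if hasattr(rec, "raw") else rec[item_id]
        if raw is None:
            raise ValueError(f"record {getattr(rec, 'subject_id', '?')} lacks {item_id}")
        values.append(item.normalize_raw(raw))

    if item.response_kind == "binary":
        counts = {"No": 0, "Yes": 0}
        for v in values:
            counts[v] += 1
    else:
        worst = max(values)
        counts = {str(r): 0 for r in range(int(worst) + 1)}
        for v in values:
            counts[str(v)] += 1
    return FrequencyTable(item_id=item_id, counts=counts, n_total=len(values))


def derive_standard_scores(freq: FrequencyTable) -> dict[str, int]:
    """Derive the raw→standard lookup from one item's normative frequencies.

    standard(best) = 100; for any worse category r, standard(r) is the
    cumulative percentage of the cohort at r or worse, rounded half-up.
    Categories never observed inherit the cumulative percentage at that point,
    so the lookup is monotone non-increasing by construction.
    """
    if not freq.counts:
        raise ValueError(f"{freq.item_id}: empty frequency table")
    n = freq.n_total
    if n <= 0:
        raise ValueError(f"{freq.item_id}: empty cohort")
    lookup: dict[str, int] = {}
    at_or_worse = n
    for i, (raw, count) in enumerate(freq.counts.items()):
        if i == 0:
            lookup[raw] = 100
        else:
            lookup[raw] = _round_half_up(100.0 * at_or_worse / n)
        at_or_worse -= count
    return lookup


def derive_norm_table(
    cohort: Sequence | None = None,
    *,
    frequency_tables: Mapping[str, FrequencyTable] | None = None,
    instrument: InstrumentSpec | None = None,
    items: Iterable[str] | None = None,
) -> NormTable:
    """Derive a full norm table, either from raw records or from frequency tables."""
    instrument = instrument or canonical_instrument()
    if frequency_tables is None:
        if cohort is None:
            raise ValueError("provide a cohort or frequency tables")
        item_ids = tuple(items) if items else instrument.item_ids
        frequency_tables = {
            i: tabulate_frequencies(cohort, i, instrument) for i in item_ids
        }
    totals = {f.n_total for f in frequency_tables.values()}
    n_total = max(totals)
    if n_total < MIN_STABLE_COHORT:
        logger.warning(
            "normative cohort has n=%d (<%d); percentile scores will be unstable",
            n_total, MIN_STABLE_COHORT,
        )
    lookups = {i: derive_standard_scores(f) for i, f in frequency_tables.items()}
    return NormTable(
        lookups=lookups,
        frequencies=dict(frequency_tables),
        n_total=n_total,
    )


def frequency_tables_from_instrument(
    spec: InstrumentSpec | None = None,
) -> dict[str, FrequencyTable]:
    """Extract the normative frequency tables embedded in an instrument's bins."""
    spec = spec or canonical_instrument()
    tables = {}
    for it in spec.items:
        if any(b.count is None for b in it.bins):
            raise ValueError(f"{it.item_id}: bins carry no counts")
        tables[it.item_id] = FrequencyTable(
            item_id=it.item_id,
            counts={b.raw: int(b.count) for b in it.bins},  # type: ignore[arg-type]
            n_total=sum(int(b.count) for b in it.bins),  # type: ignore[arg-type]
        )
    return tables


@dataclass
class CellDeviation:
    item_id: str
    raw: str
    derived: int
    published: int

    @property
    def deviation(self) -> int:
        return abs(self.derived - self.published)


@dataclass
class DeviationReport:
    """Cell-by-cell comparison of a derived norm table against a published one."""

    cells: list[CellDeviation]
    tolerance: int

    @property
    def max_deviation(self) -> int:
        return max((c.deviation for c in self.cells), default=0)

    @property
    def flagged(self) -> list[CellDeviation]:
        return [c for c in self.cells if c.deviation > self.tolerance]

    def summary(self) -> str:
        return (
            f"{len(self.cells)} cells compared; max |derived-published| = "
            f"{self.max_deviation}; {len(self.flagged)} cells exceed "
            f"tolerance {self.tolerance}"
        )


def compare_to_published(
    derived: NormTable | Mapping[str, Mapping[str, int]],
    published: InstrumentSpec | None = None,
    tolerance: int = 3,
) -> DeviationReport:
    """Compare derived standard scores against a published instrument, cell by cell.

    Raises on mismatched item sets or raw categories: a deviation report is
    only meaningful over identical category grids.
    """
    published = published or canonical_instrument()
    lookups = derived.lookups if isinstance(derived, NormTable) else derived
    cells: list[CellDeviation] = []
    for item_id, lut in lookups.items():
        item = published.item(item_id)
        pub = {b.raw: b.standard for b in item.bins}
        if set(lut) != set(pub):
            raise ValueError(
                f"{item_id}: raw categories differ "
                f"(derived {sorted(lut)}, published {sorted(pub)})"
            )
        for raw, std in lut.items():
            cells.append(CellDeviation(item_id, raw, int(std), int(pub[raw])))
    return DeviationReport(cells=cells, tolerance=tolerance)
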