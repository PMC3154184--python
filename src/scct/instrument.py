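"""Item definitions and the published norm table for the Standardized Copy of the Cube Test.

The SCCT asks a subject to copy a Necker cube (a wireframe cube drawn in
isometric perspective) and scores the copy on 14 error items — missing or
non-parallel lines, distorted angles, missing elements, rotation, mirror
imaging, closing-in, and so on.  Two further items record omission and
commission errors on the Random Letter Test (RLT), a brief vigilance task
administered alongside the drawing.

Each raw observation (an error count, or a Yes/No judgement) is converted to a
*standard score* on a 0-100 scale anchored to a normative sample of 93 healthy
adults: the standard score for a raw category is (approximately) the
percentage of the normative sample that performed that badly or worse, so 100
means error-free reference performance and low scores mean performance almost
never seen in healthy controls.

This module ships the published norm table as versioned package data and
exposes it through :func:`canonical_instrument`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

logger = logging.getLogger(__name__)

#: Item identifiers, in instrument order.
SCCT_ITEMS: tuple[str, ...] = tuple(f"SCCT-{i}" for i in range(1, 15))
RLT_ITEMS: tuple[str, ...] = ("RLT-A", "RLT-B")
ALL_ITEMS: tuple[str, ...] = SCCT_ITEMS + RLT_ITEMS

RawValue = Union[int, str, bool]

_CANONICAL_RESOURCE = "norm_table_v1.json"


def _parse_raw_label(label: str) -> tuple[int, int | None]:
    """Translate a printed raw-score label into a numeric [lower, upper] bin.

    ``"No"``/``"Yes"`` map to 0/1, ``"a-b"`` to a closed range, ``">k"`` to the
    right-open bin starting at k+1, and a plain integer to a singleton bin.
    An ``upper`` of ``None`` marks a right-open catch-all.
    """
    if label == "No":
        return 0, 0
    if label == "Yes":
        return 1, 1
    if label.startswith(">"):
        return int(label[1:]) + 1, None
    if "-" in label[1:]:  # tolerate a (never-occurring) leading minus
        lo, hi = label.split("-", 1)
        return int(lo), int(hi)
    value = int(label)
    return value, value


@dataclass(frozen=True)
class NormBin:
    """One raw-score category of an item's lookup table.

    ``raw`` is the printed category label; ``count``/``percent`` are the
    normative frequencies when known (required for norm derivation, optional
    for plain scoring).
    """

    raw: str
    standard: int
    count: int | None = None
    percent: float | None = None

    @property
    def bounds(self) -> tuple[int, int | None]:
        return _parse_raw_label(self.raw)

    @property
    def lower(self) -> int:
        return self.bounds[0]

    @property
    def upper(self) -> int | None:
        return self.bounds[1]


@dataclass(frozen=True)
class ItemDefinition:
    """Identity, response kind, and raw→standard lookup for one item.

    ``response_kind`` is ``"count"`` (non-negative error counts) or
    ``"binary"`` (a Yes/No judgement, Yes being the anomaly).  ``raw_max``
    carries the instrument's "maximum N" annotation where one exists; it is
    informational — scoring clamps into the final catch-all bin regardless.
    """

    item_id: str
    label: str
    response_kind: str  # "count" | "binary"
    bins: tuple[NormBin, ...]
    raw_max: int | None = None

    def __post_init__(self) -> None:
        if self.response_kind not in ("count", "binary"):
            raise ValueError(f"unknown response kind {self.response_kind!r}")
        if not self.bins:
            raise ValueError(f"{self.item_id}: no bins")

    def normalize_raw(self, raw: RawValue) -> RawValue:
        """Coerce a raw observation to the item's canonical form.

        Binary items accept No/Yes (case-insensitive), 0/1 and booleans and
        return ``"No"``/``"Yes"``; count items accept non-negative integers.
        """
        if self.response_kind == "binary":
            if isinstance(raw, str):
                low = raw.strip().lower()
                if low in ("no", "0", "false"):
                    return "No"
                if low in ("yes", "1", "true"):
                    return "Yes"
            elif raw in (0, False):
                return "No"
            elif raw in (1, True):
                return "Yes"
            raise ValueError(
                f"{self.item_id}: binary item takes Yes/No (or 0/1), got {raw!r}"
            )
        if isinstance(raw, bool) or not isinstance(raw, (int,)):
            try:
                as_int = int(str(raw).strip())
            except (TypeError, ValueError):
                raise ValueError(
                    f"{self.item_id}: count item takes a non-negative integer, got {raw!r}"
                ) from None
        else:
            as_int = raw
        if as_int < 0:
            raise ValueError(f"{self.item_id}: negative count {as_int}")
        return as_int

    def lookup(self, raw: RawValue) -> int:
        """Standard score for a raw observation.

        Counts at or beyond the final bin's lower edge clamp into that bin
        (the catch-all rows of the norm table are terminal); the clamp is
        logged at INFO level.
        """
        raw = self.normalize_raw(raw)
        if self.response_kind == "binary":
            for b in self.bins:
                if b.raw == raw:
                    return b.standard
            raise ValueError(f"{self.item_id}: no bin for {raw!r}")
        for b in self.bins:
            upper = b.upper
            if b.lower <= raw and (upper is None or raw <= upper):
                return b.standard
        last = self.bins[-1]
        if raw > last.lower:
            logger.info(
                "%s: raw value %s beyond last category %r, clamped",
                self.item_id, raw, last.raw,
            )
            return last.standard
        raise ValueError(f"{self.item_id}: no bin covers raw value {raw!r}")

    @property
    def worst_standard(self) -> int:
        return min(b.standard for b in self.bins)


@dataclass(frozen=True)
class InstrumentSpec:
    """The full instrument: 16 items plus the subscale and index composition.

    The five subscales group the 14 drawing items by their factor structure
    (Missing Elements, Deformation, Mirror Image, Rotation, Close-In); the
    three indices group the subscales (Deficit, Deformation, Closing-In).
    The RLT items stand outside both.
    """

    items: tuple[ItemDefinition, ...]
    subscales: Mapping[str, tuple[str, ...]]
    indices: Mapping[str, tuple[str, ...]]
    version: str = "1.0"
    n_normative: int | None = None
    _by_id: Mapping[str, ItemDefinition] = field(
        init=False, repr=False, compare=False, default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_id", {it.item_id: it for it in self.items})

    def item(self, item_id: str) -> ItemDefinition:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise KeyError(f"unknown item id {item_id!r}") from None

    def lookup(self, item_id: str, raw: RawValue) -> int:
        return self.item(item_id).lookup(raw)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def scct_item_ids(self) -> tuple[str, ...]:
        return tuple(i for i in self.item_ids if i.startswith("SCCT-"))

    # ---- serialization (norm-table JSON schema) ----

    def to_dict(self) -> dict:
        doc: dict = {
            "version": self.version,
            "items": [
                {
                    "id": it.item_id,
                    "label": it.label,
                    "kind": it.response_kind,
                    "raw_max": it.raw_max,
                    "bins": [
                        {k: v for k, v in
                         (("raw", b.raw), ("count", b.count),
                          ("percent", b.percent), ("standard", b.standard))
                         if v is not None}
                        for b in it.bins
                    ],
                }
                for it in self.items
            ],
            "subscales": {k: list(v) for k, v in self.subscales.items()},
            "indices": {k: list(v) for k, v in self.indices.items()},
        }
        if self.n_normative is not None:
            doc["n_normative"] = self.n_normative
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "InstrumentSpec":
        items = tuple(
            ItemDefinition(
                item_id=i["id"],
                label=i.get("label", i["id"]),
                response_kind=i["kind"],
                raw_max=i.get("raw_max"),
                bins=tuple(
                    NormBin(
                        raw=str(b["raw"]),
                        standard=int(b["standard"]),
                        count=b.get("count"),
                        percent=b.get("percent"),
                    )
                    for b in i["bins"]
                ),
            )
            for i in doc["items"]
        )
        return cls(
            items=items,
            subscales={k: tuple(v) for k, v in doc["subscales"].items()},
            indices={k: tuple(v) for k, v in doc["indices"].items()},
            version=str(doc.get("version", "?")),
            n_normative=doc.get("n_normative"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "InstrumentSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@lru_cache(maxsize=1)
def canonical_instrument() -> InstrumentSpec:
    """The published instrument: 14 SCCT items + 2 RLT items with their norm table."""
    text = resources.files("scct.data").joinpath(_CANONICAL_RESOURCE).read_text()
    return InstrumentSpec.from_dict(json.loads(text))


def validate_instrument(spec: InstrumentSpec) -> list[str]:
    """Check every instrument invariant; return human-readable violations.

    An empty list means the instrument is internally consistent.  Violations are
    data, not exceptions: the function never raises on bad content.
    """
    violations: list[str] = []
    for it in spec.items:
        stds = [b.standard for b in it.bins]
        first = it.bins[0]
        if first.raw not in ("0", "No"):
            violations.append(
                f"{it.item_id}: first raw category must be 0/'No', got {first.raw!r}"
            )
        if first.standard != 100:
            violations.append(
                f"{it.item_id}: raw 0 must map to 100, got {first.standard}"
            )
        for a, b in zip(it.bins, it.bins[1:]):
            if b.standard > a.standard:
                violations.append(
                    f"{it.item_id}: standard scores must be non-increasing "
                    f"({a.raw!r}→{a.standard} then {b.raw!r}→{b.standard})"
                )
        for b in it.bins:
            if not 0 <= b.standard <= 100:
                violations.append(
                    f"{it.item_id}: standard score {b.standard} outside [0, 100] "
                    f"at raw {b.raw!r}"
                )

    scct_ids = set(spec.scct_item_ids)
    seen: dict[str, str] = {}
    for sub, members in spec.subscales.items():
        for m in members:
            if m in seen:
                violations.append(
                    f"item {m} appears in subscales {seen[m]} and {sub}"
                )
            seen[m] = sub
            if m.startswith("RLT"):
                violations.append(f"RLT item {m} must not belong to subscale {sub}")
    missing = scct_ids - set(seen)
    if missing:
        violations.append(f"SCCT items in no subscale: {sorted(missing)}")

    seen_sub: dict[str, str] = {}
    for idx, members in spec.indices.items():
        for s in members:
            if s in seen_sub:
                violations.append(
                    f"subscale {s} appears in indices {seen_sub[s]} and {idx}"
                )
            seen_sub[s] = idx
    orphan = set(spec.subscales) - set(seen_sub)
    if orphan:
        violations.append(f"subscales in no index: {sorted(orphan)}")
    return violations
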