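"""Access to the published group-level score profiles shipped with the package.

The instrument's validation study reported group means and SDs for every
item, subscale, index and the total: for the whole normative sample and the
whole patient sample (subscale/index level), and for the two age strata
("below 41" vs "above 40", the boundary age belonging to the younger
stratum).  These printed summaries are the only group-level data available
for the instrument; they serve as calibration targets for the synthetic
cohort generator and as fixed inputs for consistency checks of the
subscale/index composition rules.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Mapping

from .instrument import InstrumentSpec, canonical_instrument

_RESOURCE = "published_profiles.json"

#: Valid stratum keys of the age-split tables.
STRATA = ("below_41", "above_40")


@lru_cache(maxsize=1)
def published_profiles() -> dict:
    """The full published profile document (means, SDs, group sizes)."""
    text = resources.files("scct.data").joinpath(_RESOURCE).read_text()
    return json.loads(text)


def group_means(
    group: str,
    stratum: str | None = None,
) -> dict[str, float]:
    """Published mean profile for one group.

    ``stratum`` of ``None`` returns the whole-sample subscale/index means;
    ``"below_41"``/``"above_40"`` return the full per-item age-split blocks.
    """
    doc = published_profiles()
    if stratum is None:
        return dict(doc["whole_sample"][group]["mean"])
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    return dict(doc["age_split"][stratum][group]["mean"])


def group_n(group: str, stratum: str | None = None) -> int:
    doc = published_profiles()
    block = doc["whole_sample"] if stratum is None else doc["age_split"][stratum]
    return int(block[group]["n"])


def patient_item_targets(stratum: str = "below_41") -> dict[str, float]:
    """Per-item patient means usable as synthetic-calibration targets."""
    means = group_means("patient", stratum)
    return {k: v for k, v in means.items() if k.startswith("SCCT-") or k.startswith("RLT-")}


def compose_index_means(
    subscale_means: Mapping[str, float],
    instrument: InstrumentSpec | None = None,
) -> dict[str, float]:
    """Apply the index composition rule (index = sum of its subscales) to a mean profile.

    Valid because the indices are linear in the subscales, so the rule holds
    for group means exactly as it does for individual records.
    """
    instrument = instrument or canonical_instrument()
    out = {}
    for idx, members in instrument.indices.items():
        missing = [m for m in members if m not in subscale_means]
        if missing:
            raise KeyError(f"{idx}: no mean given for subscales {missing}")
        out[idx] = round(float(sum(subscale_means[m] for m in members)), 2)
    return out
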