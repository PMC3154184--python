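import pytest
from hypothesis import settings

from scct import SubjectRawRecord, canonical_instrument

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def instrument():
    return canonical_instrument()


def make_raw_record(subject_id="s1", group="control", age=None, **overrides):
    """A perfect (error-free) raw record with selected items overridden.

    Overrides use item ids with '_' for '-' (scct_3=4) or exact ids via the
    raw dict afterwards.
    """
    raw = {f"SCCT-{i}": 0 for i in range(1, 12)}
    raw.update({"SCCT-12": "No", "SCCT-13": "No", "SCCT-14": "No",
                "RLT-A": 0, "RLT-B": 0})
    for key, value in overrides.items():
        item_id = key.replace("_", "-").upper()
        if item_id not in raw:
            raise KeyError(item_id)
        raw[item_id] = value
    return SubjectRawRecord(subject_id=subject_id, raw=raw, group=group, age=age)


@pytest.fixture
def perfect_record():
    return make_raw_record()
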