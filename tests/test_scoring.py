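"""Standardization, aggregation, letter series and cohort summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scct import (
    RANDOM_LETTER_SERIES,
    LetterSeries,
    cohort_summary,
    count_target_letters,
    normative_marginal_cohort,
    score_rlt,
    standardize_cohort,
    standardize_record,
)
from tests.conftest import make_raw_record


class TestStandardize:
    def test_perfect_performance(self, perfect_record):
        rec = standardize_record(perfect_record)
        assert all(v == 100 for v in rec.item_scores.values())
        assert rec.subscales == {"ME": 400, "D": 700, "M": 100, "R": 100, "CI": 100}
        assert rec.indices == {"DcI": 500, "DfI": 800, "CiI": 100}
        assert rec.scct_total == 1400
        assert rec.rlt_a == 100 and rec.rlt_b == 100

    def test_rotation_only_error(self):
        rec = standardize_record(make_raw_record(scct_12="Yes"))
        assert rec.subscales["R"] == 20
        assert rec.indices["DfI"] == 720
        assert rec.scct_total == 1320

    def test_two_count_errors(self):
        rec = standardize_record(make_raw_record(scct_3=4, scct_5=1))
        assert rec.item_scores["SCCT-3"] == 40
        assert rec.item_scores["SCCT-5"] == 50
        assert rec.scct_total == 1400 - 60 - 50

    def test_missing_item_is_hard_error(self, perfect_record):
        del perfect_record.raw["SCCT-7"]
        with pytest.raises(ValueError, match="SCCT-7"):
            standardize_record(perfect_record)

    def test_prorating_is_explicit_and_flagged(self, perfect_record):
        del perfect_record.raw["SCCT-7"]
        rec = standardize_record(perfect_record, prorate_missing=True)
        assert rec.prorated
        assert rec.scct_total == pytest.approx(1300 * 14 / 13)

    def test_unknown_item_rejected(self, perfect_record):
        perfect_record.raw["SCCT-99"] = 0
        with pytest.raises(KeyError):
            standardize_record(perfect_record)

    @given(
        counts=st.tuples(*[st.integers(min_value=0, max_value=30)] * 11),
        binaries=st.tuples(*[st.booleans()] * 3),
    )
    @settings(max_examples=80, deadline=None)
    def test_additivity_and_bounds_hold_for_any_record(self, counts, binaries):
        """DcI = ME + M, DfI = D + R, total = sum of the 14 item scores, and
        every aggregate stays inside its structural range."""
        overrides = {f"scct_{i + 1}": c for i, c in enumerate(counts)}
        overrides.update({f"scct_{i + 12}": "Yes" if b else "No"
                          for i, b in enumerate(binaries)})
        rec = standardize_record(make_raw_record(**overrides))
        s, x = rec.subscales, rec.indices
        assert x["DcI"] == s["ME"] + s["M"]
        assert x["DfI"] == s["D"] + s["R"]
        assert x["CiI"] == s["CI"]
        assert rec.scct_total == sum(rec.item_scores.values())
        assert 0 <= s["ME"] <= 400 and 0 <= s["D"] <= 700
        assert 0 <= rec.scct_total <= 1400


class TestLetterSeries:
    def test_printed_series_target_counts(self):
        assert [count_target_letters(s) for s in RANDOM_LETTER_SERIES] == [5, 4, 5, 4]

    def test_no_targets(self):
        assert count_target_letters("BBBB") == 0

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            LetterSeries("")
        with pytest.raises(ValueError):
            LetterSeries("AB1C")
        with pytest.raises(ValueError):
            LetterSeries("ABC", target="AB")


class TestRLT:
    @pytest.mark.parametrize(
        "omissions,intrusions,expected",
        [(0, 0, (100, 100)), (0, 1, (100, 8)), (2, 5, (0, 0)), (1, 2, (0, 1))],
    )
    def test_published_rlt_lookups(self, omissions, intrusions, expected):
        assert score_rlt(omissions, intrusions) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            score_rlt(-1, 0)


class TestCohortSummary:
    def test_identical_perfect_records(self):
        scored = standardize_cohort([make_raw_record(f"s{i}") for i in range(4)])
        summary = cohort_summary(scored)
        assert summary.loc["SCCT-3", ("control", "mean")] == 100
        assert summary.loc["SCCT", ("control", "sd")] == 0
        assert summary.loc["SCCT", ("control", "n")] == 4

    def test_normative_frequencies_give_published_binary_means(self):
        """A cohort laid out at the exact normative frequencies reproduces the
        frequency-weighted Rotation and Mirror Image subscale means."""
        scored = standardize_cohort(normative_marginal_cohort())
        summary = cohort_summary(scored)
        assert round(summary.loc["R", ("control", "mean")], 2) == 83.66
        assert round(summary.loc["M", ("control", "mean")], 2) == 95.87

    def test_index_means_add_across_groups(self):
        cohort = [make_raw_record(f"c{i}", scct_13="Yes" if i % 2 else "No")
                  for i in range(6)]
        cohort += [make_raw_record(f"p{i}", group="patient", scct_1=i, scct_13="Yes")
                   for i in range(5)]
        summary = cohort_summary(standardize_cohort(cohort))
        for group in ("control", "patient"):
            assert summary.loc["DcI", (group, "mean")] == pytest.approx(
                summary.loc["ME", (group, "mean")] + summary.loc["M", (group, "mean")]
            )

    def test_age_split_boundary_in_younger_stratum(self):
        cohort = [make_raw_record("a", age=40), make_raw_record("b", age=41)]
        summary = cohort_summary(standardize_cohort(cohort), split_age=40)
        assert summary.loc["SCCT", ("control", "<=40", "n")] == 1
        assert summary.loc["SCCT", ("control", ">40", "n")] == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])
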