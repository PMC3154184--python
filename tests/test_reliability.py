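"""Internal consistency and inter-rater agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scct import RatingsMatrix, cronbach_alpha, interrater

# 4 subjects x 3 items; expected alpha frozen from an independent spreadsheet-style
# computation of k/(k-1) * (1 - sum(item variances)/variance(total)) with n-1 variances.
SMALL_MATRIX = pd.DataFrame(
    [[2, 3, 4], [4, 5, 5], [6, 5, 7], [8, 9, 9]], columns=["i1", "i2", "i3"]
)
SMALL_MATRIX_ALPHA = 0.9789983844911148


class TestAlpha:
    def test_small_matrix_matches_independent_computation(self):
        result = cronbach_alpha(SMALL_MATRIX)
        assert result.alpha == pytest.approx(SMALL_MATRIX_ALPHA, abs=1e-12)
        assert set(result.alpha_if_deleted) == {"i1", "i2", "i3"}

    def test_cross_check_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        expected = pingouin.cronbach_alpha(SMALL_MATRIX)[0]
        assert cronbach_alpha(SMALL_MATRIX).alpha == pytest.approx(expected)

    def test_parallel_items_give_alpha_one(self):
        col = [1.0, 4.0, 2.0, 7.0, 3.0]
        frame = pd.DataFrame({"a": col, "b": col, "c": col})
        assert cronbach_alpha(frame).alpha == pytest.approx(1.0)

    def test_independent_noise_gives_alpha_near_zero(self):
        rng = np.random.default_rng(20110719)
        frame = pd.DataFrame(rng.normal(size=(5000, 2)), columns=["a", "b"])
        assert abs(cronbach_alpha(frame).alpha) < 0.05

    def test_zero_variance_items_dropped_with_warning(self, caplog):
        import logging

        frame = SMALL_MATRIX.assign(flat=1.0)
        with caplog.at_level(logging.WARNING, logger="scct.reliability"):
            result = cronbach_alpha(frame)
        assert result.dropped_items == ["flat"]
        assert result.alpha == pytest.approx(SMALL_MATRIX_ALPHA, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):  # too few subjects
            cronbach_alpha(SMALL_MATRIX.iloc[:2])
        with pytest.raises(ValueError):  # a single usable item
            cronbach_alpha(pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [1, 1, 1]}))

    @given(
        shift=st.floats(min_value=-50, max_value=50, allow_nan=False),
        order=st.permutations(["i1", "i2", "i3"]),
    )
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_item_shift_and_reordering(self, shift, order):
        shifted = SMALL_MATRIX.copy()
        shifted["i2"] = shifted["i2"] + shift
        assert cronbach_alpha(shifted[list(order)]).alpha == pytest.approx(
            SMALL_MATRIX_ALPHA, abs=1e-9
        )


def _matrix(data, rater="A"):
    return RatingsMatrix(pd.DataFrame(data), rater_id=rater)


class TestInterrater:
    def test_identical_ratings(self):
        m = _matrix({"i1": [1.0, 2, 3, 4], "i2": [4.0, 3, 2, 1]})
        report = interrater(m, _matrix(m.scores, "B"))
        assert report.item_r == {"i1": pytest.approx(1.0), "i2": pytest.approx(1.0)}
        assert report.total_r is None  # totals are constant here
        assert all(v == 0 for v in report.diff_mean.values())

    def test_constant_shift_is_perfect_correlation_not_agreement(self):
        a = _matrix({"i1": [1.0, 2, 3, 4]})
        b = _matrix({"i1": [6.0, 7, 8, 9]}, "B")
        report = interrater(a, b)
        assert report.item_r["i1"] == pytest.approx(1.0)
        assert report.diff_mean["i1"] == pytest.approx(5.0)
        assert report.diff_sd["i1"] == pytest.approx(0.0)

    def test_anticorrelated_columns(self):
        report = interrater(
            _matrix({"i1": [1.0, 2, 3]}), _matrix({"i1": [3.0, 2, 1]}, "B")
        )
        assert report.item_r["i1"] == pytest.approx(-1.0)

    def test_zero_variance_item_reported_undefined(self):
        report = interrater(
            _matrix({"i1": [1.0, 1, 1], "i2": [1.0, 2, 3]}),
            _matrix({"i1": [1.0, 2, 3], "i2": [2.0, 4, 6]}, "B"),
        )
        assert "i1" in report.undefined_items
        assert "i1" not in report.item_r
        assert report.item_r["i2"] == pytest.approx(1.0)

    def test_swap_symmetry_negates_differences(self):
        a = _matrix({"i1": [1.0, 5, 2], "i2": [2.0, 1, 4]})
        b = _matrix({"i1": [2.0, 4, 2], "i2": [1.0, 3, 3]}, "B")
        fwd, rev = interrater(a, b), interrater(b, a)
        assert fwd.item_r == pytest.approx(rev.item_r)
        for item in fwd.diff_mean:
            assert fwd.diff_mean[item] == pytest.approx(-rev.diff_mean[item])

    def test_pairs_reconstruct_both_ratings(self):
        a = _matrix({"i1": [1.0, 5, 2]})
        b = _matrix({"i1": [2.0, 4, 2]}, "B")
        report = interrater(a, b)
        for (avg, diff), x, y in zip(report.pairs["i1"], a.scores["i1"], b.scores["i1"]):
            assert avg - diff / 2 == pytest.approx(x)
            assert avg + diff / 2 == pytest.approx(y)

    def test_mismatched_raters_rejected(self):
        with pytest.raises(ValueError):
            interrater(_matrix({"i1": [1.0, 2]}), _matrix({"i2": [1.0, 2]}, "B"))


def test_missing_cells_rejected():
    with pytest.raises(ValueError):
        RatingsMatrix(pd.DataFrame({"i1": [1.0, np.nan]}))
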