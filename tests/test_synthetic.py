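"""Synthetic cohort generator: anchoring, calibration, determinism."""

import numpy as np
import pytest

from scct import (
    SimulationConfig,
    calibrate_patient_profile,
    canonical_instrument,
    control_profile,
    expected_item_mean,
    patient_profile,
    sample_cohort,
    standardize_cohort,
)
from scct.reference import patient_item_targets


class TestExpectedMeans:
    def test_severity_zero_equals_frequency_weighted_mean(self, instrument):
        """At severity 0 the closed-form expected standardized mean of every
        item equals the frequency-weighted average of its standard scores."""
        profile = control_profile(instrument)
        for item in instrument.items:
            counts = np.array([b.count for b in item.bins], dtype=float)
            standards = np.array([b.standard for b in item.bins], dtype=float)
            expected = float(counts @ standards / counts.sum())
            assert expected_item_mean(profile, item) == pytest.approx(expected)

    def test_rotation_and_mirror_anchors(self, instrument):
        profile = control_profile(instrument)
        rotation = expected_item_mean(profile, instrument.item("SCCT-12"))
        mirror = expected_item_mean(profile, instrument.item("SCCT-13"))
        assert round(rotation, 2) == 83.66
        assert round(mirror, 2) == 95.87

    def test_mean_monotone_nonincreasing_in_severity(self, instrument):
        profile = control_profile(instrument)
        for item in instrument.items:
            means = [expected_item_mean(profile, item, lam=l)
                     for l in np.linspace(0, 1, 11)]
            assert all(a >= b - 1e-9 for a, b in zip(means, means[1:])), item.item_id


class TestSampling:
    def test_same_seed_identical_cohorts(self):
        config = SimulationConfig(n_control=25, n_patient=25, seed=11)
        assert sample_cohort(config) == sample_cohort(config)

    def test_different_seed_differs(self):
        a = sample_cohort(SimulationConfig(n_control=40, n_patient=0, seed=1))
        b = sample_cohort(SimulationConfig(n_control=40, n_patient=0, seed=2))
        assert a != b

    def test_empty_cohort(self):
        assert sample_cohort(SimulationConfig(n_control=0, n_patient=0, seed=3)) == []

    def test_large_control_cohort_recovers_rotation_mean(self, instrument):
        """Law of large numbers: 10^4 seeded controls put the standardized
        Rotation mean within 2 points of the frequency-weighted 83.66."""
        cohort = sample_cohort(SimulationConfig(n_control=10_000, n_patient=0, seed=93))
        scored = standardize_cohort(cohort)
        rotation_mean = np.mean([r.subscales["R"] for r in scored])
        assert abs(rotation_mean - 83.66) < 2.0

    def test_coupled_mode_induces_positive_rank_correlation(self, instrument):
        """A shared per-subject severity draw couples failures across the
        deformation items, unlike the independent mode."""
        config = SimulationConfig(
            n_control=0, n_patient=1500, seed=5, severity=0.5, correlation="coupled"
        )
        scored = standardize_cohort(sample_cohort(config))
        s2 = np.array([r.item_scores["SCCT-2"] for r in scored])
        s8 = np.array([r.item_scores["SCCT-8"] for r in scored])
        coupled_r = np.corrcoef(s2, s8)[0, 1]
        config_ind = SimulationConfig(n_control=0, n_patient=1500, seed=5, severity=0.5)
        scored_ind = standardize_cohort(sample_cohort(config_ind))
        i2 = np.array([r.item_scores["SCCT-2"] for r in scored_ind])
        i8 = np.array([r.item_scores["SCCT-8"] for r in scored_ind])
        independent_r = np.corrcoef(i2, i8)[0, 1]
        assert coupled_r > 0.3
        assert coupled_r > independent_r + 0.2

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_control=-1, n_patient=0, seed=1)
        with pytest.raises(ValueError):
            SimulationConfig(n_control=1, n_patient=1, seed=1, correlation="magic")
        with pytest.raises(ValueError):
            patient_profile(severity=1.5)


class TestCalibration:
    def test_target_100_selects_severity_zero(self):
        _, report = calibrate_patient_profile({"SCCT-14": 100.0})
        assert report.lam["SCCT-14"] == 0.0

    def test_target_at_worst_category_selects_severity_one(self, instrument):
        worst = instrument.item("SCCT-13").worst_standard  # mirror image: 4
        profile, report = calibrate_patient_profile({"SCCT-13": float(worst)})
        assert report.lam["SCCT-13"] == pytest.approx(1.0)
        assert report.achieved["SCCT-13"] == pytest.approx(worst)

    def test_published_patient_mean_reached_within_five_points(self, instrument):
        _, report = calibrate_patient_profile({"SCCT-5": 31.45})
        assert abs(report.achieved["SCCT-5"] - 31.45) < 5.0
        assert not report.unattainable

    def test_calibration_matches_grid_search_oracle(self, instrument):
        """Bisection agrees with an exhaustive severity-grid evaluation."""
        base = control_profile(instrument)
        item = instrument.item("SCCT-5")
        target = 31.45
        grid = np.linspace(0, 1, 100_001)
        grid_means = np.array([expected_item_mean(base, item, lam=l) for l in grid])
        best = grid[np.argmin(np.abs(grid_means - target))]
        _, report = calibrate_patient_profile({"SCCT-5": target})
        assert report.lam["SCCT-5"] == pytest.approx(best, abs=1e-4)

    def test_unattainable_target_reported_not_clipped_silently(self):
        # SCCT-9 printed patient mean exceeds the severity-0 control mean
        _, report = calibrate_patient_profile({"SCCT-9": 79.89})
        assert report.lam["SCCT-9"] == 0.0
        assert "SCCT-9" in report.unattainable

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_patient_profile({"SCCT-5": 120.0})

    def test_full_published_profile_calibrates_close(self):
        targets = patient_item_targets()
        _, report = calibrate_patient_profile(targets)
        attainable = {k: v for k, v in report.target.items()
                      if k not in report.unattainable}
        for item_id, target in attainable.items():
            assert abs(report.achieved[item_id] - target) < 5.0, item_id
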