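"""Synthetic cohort generator: demographics, truth maps, noise, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from conftest import noise_free_truths, scaled_config
from vfnorm.cohort import (
    AGE_BINS,
    DEFAULT_AGE_BIN_COUNTS,
    age_mixture_moments,
    default_config,
    default_truth,
    sample_demographics,
    simulate_cohort,
    simulate_test,
    skew_noise,
    true_threshold,
)
from vfnorm.errors import ConfigError
from vfnorm.patterns import build_pattern
from vfnorm.records import Eye, ExclusionReason, PatternId


class TestDemographics:
    def test_default_bin_counts_exact(self):
        rng = np.random.default_rng(0)
        subjects = sample_demographics(default_config(), rng)
        assert len(subjects) == 356
        in_60s = [s for s in subjects if 60 <= s.age <= 69]
        assert len(in_60s) == 62
        for (lo, hi), count in zip(AGE_BINS, DEFAULT_AGE_BIN_COUNTS):
            assert sum(lo <= s.age <= hi for s in subjects) == count

    def test_all_zero_bins_give_empty_cohort(self):
        config = default_config(age_bin_counts=(0,) * 7, monocular_only_count=0)
        assert sample_demographics(config, np.random.default_rng(0)) == []

    def test_negative_bin_count_rejected(self):
        with pytest.raises(ConfigError):
            default_config(age_bin_counts=(59, 51, 56, 52, 62, 53, -1))

    def test_mean_age_matches_design(self):
        means = []
        for seed in range(1, 11):
            subjects = sample_demographics(
                default_config(), np.random.default_rng(seed)
            )
            means.append(np.mean([s.age for s in subjects]))
        assert np.mean(means) == pytest.approx(52.3, abs=1.0)

    def test_age_mixture_moments_against_enumeration(self):
        # brute-force oracle: enumerate every (bin, integer age) outcome
        weights, ages = [], []
        for count, (lo, hi) in zip(DEFAULT_AGE_BIN_COUNTS, AGE_BINS):
            for a in range(lo, hi + 1):
                ages.append(a)
                weights.append(count / (hi - lo + 1))
        w = np.array(weights) / np.sum(weights)
        a = np.array(ages, dtype=float)
        mean = float(w @ a)
        sd = float(np.sqrt(w @ a**2 - mean**2))
        got_mean, got_sd = age_mixture_moments()
        assert got_mean == pytest.approx(mean, abs=1e-12)
        assert got_sd == pytest.approx(sd, abs=1e-12)

    def test_eligible_fields_within_ranges(self):
        subjects = sample_demographics(default_config(), np.random.default_rng(3))
        for s in subjects:
            assert -0.1 <= s.va_logmar <= 0.3
            assert all(10 <= v <= 21 for v in s.iop_mmhg)
            assert all(abs(v) <= 6 for v in s.se_diopters)
            assert all(abs(v) <= 2.5 for v in s.cyl_diopters)


class TestTruthCalibration:
    @pytest.mark.parametrize(
        "pid,mean,ms", [(PatternId.P24_2, 0.06, 29.1), (PatternId.P10_2, 0.05, 32.4)]
    )
    def test_slope_and_base_map_calibration_exact(self, pid, mean, ms):
        truth = default_truth(pid)
        pattern = build_pattern(pid)
        an = np.array(pattern.analyzed_indices)
        slopes = np.array(truth.slope_map)[an]
        assert slopes.mean() == pytest.approx(mean, abs=1e-12)
        assert slopes.std(ddof=0) == pytest.approx(0.01, abs=1e-12)
        assert np.array(truth.base_map)[an].mean() == pytest.approx(ms, abs=1e-12)
        assert slopes.min() > 0

    def test_24_2_max_30_year_decline_is_2_5_db(self):
        truth = default_truth(PatternId.P24_2)
        assert 30.0 * max(truth.slope_map) == pytest.approx(2.5, abs=1e-12)

    def test_sigma_positive_and_nondecreasing_in_eccentricity(self):
        for pid in PatternId:
            truth = default_truth(pid)
            pattern = build_pattern(pid)
            ecc = np.array(pattern.eccentricities())
            sigma = np.array(truth.sigma_map)
            assert (sigma > 0).all()
            order = np.argsort(ecc)
            assert (np.diff(sigma[order]) >= -1e-12).all()

    def test_true_threshold_linearity(self):
        truth = default_truth(PatternId.P24_2)
        for j in (0, 17, 53):
            at_ref = true_threshold(truth, j, truth.reference_age)
            assert at_ref == pytest.approx(truth.base_map[j], abs=1e-12)
            diff = true_threshold(truth, j, 50) - true_threshold(truth, j, 80)
            assert diff == pytest.approx(30 * truth.slope_map[j], abs=1e-12)


class TestNoiseModel:
    def test_skew_noise_moments(self):
        rng = np.random.default_rng(5)
        x = skew_noise(rng, 0.5, 200_000)
        assert np.mean(x) == pytest.approx(0.0, abs=0.01)
        assert np.std(x) == pytest.approx(1.0, abs=0.01)
        assert stats.skew(x) < -0.2  # left tail heavier

    def test_gamma_zero_is_symmetric(self):
        rng = np.random.default_rng(6)
        x = skew_noise(rng, 0.0, 200_000)
        assert abs(stats.skew(x)) < 0.02

    def test_extreme_percentiles_asymmetric_when_skewed(self):
        rng = np.random.default_rng(7)
        x = skew_noise(rng, 0.5, 200_000)
        lo, hi = np.percentile(x, [0.5, 99.5])
        assert abs(lo) > abs(hi)

    def test_noise_free_simulation_reproduces_truth(self):
        truths = noise_free_truths()
        config = scaled_config(seed=2)
        config.truths = truths
        truth = truths[PatternId.P24_2]
        subjects = sample_demographics(config, np.random.default_rng(2))
        rec = simulate_test(
            subjects[0], truth, Eye.OD, np.random.default_rng(3), config=config
        )
        expected = [
            true_threshold(truth, j, subjects[0].age) for j in range(54)
        ]
        assert rec.values == pytest.approx(expected, abs=1e-12)
        assert rec.foveal_db == pytest.approx(
            truth.foveal_base
            - truth.foveal_slope * (subjects[0].age - truth.reference_age),
            abs=1e-12,
        )

    def test_pointwise_sd_grows_with_eccentricity(self):
        truth = default_truth(PatternId.P24_2)
        pattern = build_pattern(PatternId.P24_2)
        ecc = np.array(pattern.eccentricities())
        an = np.array(pattern.analyzed_indices)
        j_central = an[np.argmin(ecc[an])]
        j_edge = an[np.argmax(ecc[an])]
        config = default_config(seed=0)
        subj = sample_demographics(config, np.random.default_rng(0))[0]
        rng = np.random.default_rng(10)
        draws = np.array(
            [
                simulate_test(subj, truth, Eye.OD, rng, config=config, g_std=0.0).values
                for _ in range(400)
            ]
        )
        assert draws[:, j_edge].std() > draws[:, j_central].std()
        # CLT check against the configured sigma at the central point
        se = truth.sigma_map[j_central] / np.sqrt(2 * (400 - 1))
        assert draws[:, j_central].std(ddof=1) == pytest.approx(
            truth.sigma_map[j_central], abs=4 * se
        )


class TestCohortStructure:
    def test_enrollment_structure(self, cohort1):
        assert len(cohort1.subjects) == 376
        included = cohort1.included_subjects()
        assert len(included) == 356
        excluded = [
            s for s in cohort1.subjects
            if s.exclusion_reason is not ExclusionReason.NONE
        ]
        assert len(excluded) == 20
        assert sum(not s.binocular_capable for s in included) == 15

    def test_each_included_subject_has_eight_tests(self, cohort1):
        per_subject = {}
        for t in cohort1.tests:
            per_subject.setdefault(t.subject_id, []).append(t)
        included_ids = {s.subject_id for s in cohort1.included_subjects()}
        assert set(per_subject) == included_ids
        for tests in per_subject.values():
            assert len(tests) == 8  # 2 patterns x 2 eyes x (practice + study)
            assert sum(t.is_practice for t in tests) == 4

    def test_values_and_rates_within_bounds(self, cohort1):
        for t in cohort1.tests[:200]:
            assert all(0.0 <= v <= 40.0 for v in t.values)
            assert 0.0 <= min(t.fl_rate, t.fp_rate, t.fn_rate)
            assert max(t.fl_rate, t.fp_rate, t.fn_rate) <= 1.0
            assert t.duration_min > 0

    def test_same_seed_reproduces_cohort_exactly(self):
        config = scaled_config(seed=9)
        a = simulate_cohort(config)
        b = simulate_cohort(scaled_config(seed=9))
        assert a.subjects == b.subjects
        assert a.tests == b.tests

    def test_mean_sensitivity_calibration_one_seed(self, cohort1):
        pattern = build_pattern(PatternId.P24_2)
        an = list(pattern.analyzed_indices)
        values = np.array(
            [t.values for t in cohort1.tests_for(PatternId.P24_2, eye=Eye.OD)]
        )
        ms = values[:, an].mean(axis=1)
        assert ms.mean() == pytest.approx(29.1, abs=0.25)
        assert ms.std(ddof=1) == pytest.approx(1.3, abs=0.25)

    def test_durations_match_configured_distribution(self, cohort1):
        d24 = [t.duration_min for t in cohort1.tests_for(PatternId.P24_2)]
        d10 = [t.duration_min for t in cohort1.tests_for(PatternId.P10_2)]
        assert np.mean(d24) == pytest.approx(3.18, abs=0.1)
        assert np.mean(d10) == pytest.approx(3.58, abs=0.1)
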