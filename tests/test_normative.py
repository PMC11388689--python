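"""Pointwise age regression, Hazen quantiles, and model construction."""

import numpy as np
import pytest

from conftest import noise_free_truths, scaled_config
from vfnorm.cohort import (
    Cohort,
    default_config,
    sample_demographics,
    simulate_cohort,
)
from vfnorm.errors import InsufficientDataError, ModelIntegrityError
from vfnorm.normative import (
    NormativeModel,
    build_reference_database,
    fit_pointwise_regression,
    nonparametric_quantile,
    predict_reference,
    select_study_eyes,
)
from vfnorm.patterns import build_pattern
from vfnorm.records import Eye, PatternId, VFTestRecord


def _toy_cohort(ages, point_value_rows):
    """Cohort of OD study tests whose every analyzed point carries the given
    per-subject value."""
    config = default_config(seed=0)
    subjects = sample_demographics(
        default_config(
            seed=0,
            age_bin_counts=(len(ages), 0, 0, 0, 0, 0, 0),
            n_excluded_by_reason={},
            monocular_only_count=0,
        ),
        np.random.default_rng(0),
    )
    tests = []
    for subj, age, value in zip(subjects, ages, point_value_rows):
        subj.age = age
        tests.append(
            VFTestRecord(
                subject_id=subj.subject_id,
                eye=Eye.OD,
                pattern_id=PatternId.P24_2,
                values=[float(value)] * 54,
                foveal_db=float(value) + 4,
                fl_rate=0.0,
                fp_rate=0.0,
                fn_rate=0.0,
                duration_min=3.0,
            )
        )
    return Cohort(subjects=subjects, tests=tests, config=config)


class TestPointwiseRegression:
    def test_three_subject_hand_ols(self):
        # ages 30/50/70, values 30/28/26: slope -0.1 dB/yr, intercept 33
        cohort = _toy_cohort([30, 50, 70], [30.0, 28.0, 26.0])
        fits = fit_pointwise_regression(cohort, PatternId.P24_2)
        assert len(fits) == 52
        for fit in fits:
            assert fit.slope == pytest.approx(-0.1, abs=1e-12)
            assert fit.intercept == pytest.approx(33.0, abs=1e-10)
            assert fit.n == 3
            assert np.mean(fit.residuals) == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_subjects_rejected(self):
        cohort = _toy_cohort([30, 50], [30.0, 28.0])
        with pytest.raises(InsufficientDataError):
            fit_pointwise_regression(cohort, PatternId.P24_2)

    def test_noise_free_cohort_recovers_truth_slopes(self):
        config = scaled_config(seed=4)
        config.truths = noise_free_truths()
        cohort = simulate_cohort(
            config, patterns=[PatternId.P24_2], include_practice=False
        )
        truth = config.truths[PatternId.P24_2]
        fits = fit_pointwise_regression(cohort, PatternId.P24_2)
        for fit in fits:
            assert fit.slope == pytest.approx(
                -truth.slope_map[fit.point_index], abs=1e-8
            )

    def test_matches_statsmodels_on_one_point(self, cohort1):
        sm = pytest.importorskip("statsmodels.api")
        eye_map = select_study_eyes(cohort1, np.random.default_rng(11))
        fits = fit_pointwise_regression(cohort1, PatternId.P24_2, eye_map=eye_map)
        from vfnorm.normative import prepare_analysis_set

        ages, values, _, _, _ = prepare_analysis_set(
            cohort1, PatternId.P24_2, eye_map=eye_map
        )
        j = fits[10].point_index
        res = sm.OLS(values[:, j], sm.add_constant(ages)).fit()
        assert fits[10].intercept == pytest.approx(res.params[0], rel=1e-10)
        assert fits[10].slope == pytest.approx(res.params[1], rel=1e-10)

    def test_recovered_mean_slope_within_2se_across_seeds(self):
        """Slope-recovery calibration: the fitted mean decline should sit
        within 2 standard errors of truth for ~95% of replicate cohorts."""
        hits = 0
        n_seeds = 20
        for seed in range(1, n_seeds + 1):
            cohort = simulate_cohort(
                default_config(seed=seed),
                patterns=[PatternId.P24_2],
                include_practice=False,
            )
            eye_map = select_study_eyes(cohort, np.random.default_rng(seed))
            fits = fit_pointwise_regression(
                cohort, PatternId.P24_2, eye_map=eye_map
            )
            mean_decline = -np.mean([f.slope for f in fits])
            # SE of the mean slope == SE of the slope of MS on age
            ms_resid = np.mean([f.residuals for f in fits], axis=0)
            ages = np.array(
                [s.age for s in cohort.included_subjects()], dtype=float
            )
            se = np.sqrt(
                ms_resid.var(ddof=2) / ((ages - ages.mean()) ** 2).sum()
            )
            if abs(mean_decline - 0.06) <= 2 * se:
                hits += 1
        assert hits >= 17  # ~95% nominal with binomial slack at n=20


class TestHazenQuantile:
    def test_1_to_100_median(self):
        assert nonparametric_quantile(np.arange(1, 101), 50) == pytest.approx(50.5)

    def test_single_value_any_level(self):
        for level in (0.5, 5, 50, 99.5):
            assert nonparametric_quantile([7.0], level) == 7.0

    def test_matches_independent_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            x = rng.normal(size=n) * rng.uniform(0.1, 10)
            level = float(rng.uniform(0.5, 99.5))
            ours = nonparametric_quantile(x, level)
            oracle = float(np.quantile(x, level / 100, method="hazen"))
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_monotone_in_level(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=37)
        qs = [nonparametric_quantile(x, l) for l in (0.5, 1, 2, 5, 50, 95, 99.5)]
        assert (np.diff(qs) >= 0).all()

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            nonparametric_quantile([], 50)
        with pytest.raises(ValueError):
            nonparametric_quantile([1.0], 0)
        with pytest.raises(ValueError):
            nonparametric_quantile([1.0], 100)


class TestReferenceDatabase:
    def test_limits_monotone_everywhere(self, model24):
        model24.validate()  # per-point tables, md/psd/foveal ordering

    def test_variability_grows_with_eccentricity(self, model24):
        pattern = model24.pattern
        ecc = np.array(pattern.eccentricities())
        an = np.array(pattern.analyzed_indices)
        j_central = an[np.argmin(ecc[an])]
        j_edge = an[np.argmax(ecc[an])]
        lim5 = model24.resid_quantiles[5.0]
        assert lim5[j_edge] < lim5[j_central] < 0

    def test_residual_distribution_left_skewed(self, model24):
        an = np.array(model24.pattern.analyzed_indices)
        lo = model24.resid_quantiles[0.5][an]
        hi = model24.resid_quantiles[99.5][an]
        # lower tail farther from zero than upper, on average and for most points
        assert np.mean(-lo) > np.mean(hi)
        assert np.mean(-lo > hi) > 0.9

    def test_prediction_linearity_and_guard(self, model24):
        j = model24.pattern.analyzed_indices[0]
        d = predict_reference(model24, j, 50) - predict_reference(model24, j, 80)
        assert d == pytest.approx(-30 * model24.slope[j], abs=1e-10)
        with pytest.warns(UserWarning):
            predict_reference(model24, j, 0.0)

    def test_recovered_mean_decline_near_truth(self, model24):
        an = np.array(model24.pattern.analyzed_indices)
        assert -np.mean(model24.slope[an]) == pytest.approx(0.06, abs=0.01)

    def test_mirror_relabelled_cohort_builds_identical_model(self):
        """Relabelling every eye and re-indexing values through the mirror
        must leave every limit unchanged (the canonical frame is lossless)."""
        config = scaled_config(seed=6)
        cohort = simulate_cohort(
            config, patterns=[PatternId.P24_2], include_practice=False
        )
        pattern = build_pattern(PatternId.P24_2)
        perm = pattern.mirror_permutation()
        flipped_tests = []
        for t in cohort.tests:
            flip_eye = Eye.OS if t.eye is Eye.OD else Eye.OD
            flipped_tests.append(
                t.copy_with(eye=flip_eye, values=[t.values[perm[i]] for i in range(54)])
            )
        flipped = Cohort(subjects=cohort.subjects, tests=flipped_tests, config=config)
        eye_map = select_study_eyes(cohort, np.random.default_rng(2))
        eye_map_flipped = {
            k: (Eye.OS if v is Eye.OD else Eye.OD) for k, v in eye_map.items()
        }
        a = build_reference_database(cohort, PatternId.P24_2, eye_map=eye_map)
        b = build_reference_database(
            flipped, PatternId.P24_2, eye_map=eye_map_flipped
        )
        np.testing.assert_allclose(a.alpha, b.alpha, atol=1e-10)
        np.testing.assert_allclose(a.slope, b.slope, atol=1e-12)
        for level in a.resid_quantiles:
            np.testing.assert_allclose(
                a.resid_quantiles[level], b.resid_quantiles[level], atol=1e-10
            )
        assert a.md_limits == b.md_limits

    def test_noise_free_cohort_degenerates_gracefully(self):
        config = scaled_config(seed=8)
        config.truths = noise_free_truths()
        cohort = simulate_cohort(
            config, patterns=[PatternId.P24_2], include_practice=False
        )
        model = build_reference_database(cohort, PatternId.P24_2)
        an = np.array(model.pattern.analyzed_indices)
        for level in (0.5, 5.0, 99.5):
            np.testing.assert_allclose(
                model.resid_quantiles[level][an], 0.0, atol=1e-8
            )
        np.testing.assert_allclose(model.s2[an], 0.01)  # variance floor

    def test_model_integrity_error_on_corruption(self, model24):
        import copy

        bad = copy.deepcopy(model24)
        level_lo, level_hi = 0.5, 5.0
        bad.resid_quantiles[level_lo], bad.resid_quantiles[level_hi] = (
            bad.resid_quantiles[level_hi],
            bad.resid_quantiles[level_lo],
        )
        with pytest.raises(ModelIntegrityError):
            bad.validate()
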