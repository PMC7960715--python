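"""Correlation, the four age models, cross-validation and prediction intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ramanclock.calibrate as cal
from ramanclock import CohortSpec, DonorRecord, simulate_cohort


def make_donors(n=132, seed=0, **kwargs):
    spec = CohortSpec(n_donors=n, replicates_per_donor=1, seed=seed, **kwargs)
    donors, _ = simulate_cohort(spec)
    return donors


def donors_from_model(model_id, coeffs, rpf_values, sexes=None):
    """Noise-free donors generated exactly from one model family."""
    donors = []
    for i, r in enumerate(rpf_values):
        sex = sexes[i] if sexes is not None else "M"
        s = 1 if sex == "M" else 0
        rows = {
            1: [1.0, r],
            2: [1.0, r, r * r],
            3: [1.0, r, r * r, s],
            4: [1.0, r, s, r * s],
        }[model_id]
        age = float(np.dot(rows, coeffs))
        donors.append(DonorRecord(f"d{i}", age, sex, rpf=float(r)))
    return donors


class TestPearson:
    def test_perfect_negative_line(self):
        x = np.linspace(0.0, 1.0, 20)
        res = cal.pearson(x, -2 * x + 5)
        assert res.r == pytest.approx(-1.0)
        assert res.p_value < 1e-10

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(1)
        res = cal.pearson(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(res.r) < 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cal.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            cal.pearson([1.0, 2.0], [1.0, 2.0])

    def test_noiseless_linear_cohort_gives_minus_one(self):
        donors = make_donors(
            n=50, seed=2, age_noise_sd=0.0, model_coefficients=(108.4, -133.8)
        )
        res = cal.pearson(
            [d.age for d in donors], [d.rpf for d in donors], ("age", "rpf")
        )
        assert res.r == pytest.approx(-1.0, abs=1e-12)


class TestFitModel:
    def test_reference_line_recovered_exactly(self):
        coeffs = cal.REFERENCE_MODELS[1]
        donors = donors_from_model(1, coeffs, [0.2, 0.35, 0.5, 0.65, 0.8])
        model = cal.fit_model(donors, 1)
        np.testing.assert_allclose(model.coefficients, coeffs, atol=1e-8)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-8)

    def test_reference_quadratic_recovered_exactly(self):
        coeffs = cal.REFERENCE_MODELS[2]
        donors = donors_from_model(2, coeffs, np.linspace(0.16, 0.9, 8))
        model = cal.fit_model(donors, 2)
        assert model.coefficients[2] == pytest.approx(99.4, abs=1e-8)

    @given(
        c0=st.floats(-50, 150),
        c1=st.floats(-300, 50),
        c2=st.floats(-50, 150),
        c3=st.floats(-10, 10),
        model_id=st.sampled_from([1, 2, 3, 4]),
    )
    @settings(derandomize=True, max_examples=40)
    def test_noiseless_recovery_all_families(self, c0, c1, c2, c3, model_id):
        coeffs = (c0, c1, c2, c3)[: len(cal.MODEL_TERMS[model_id])]
        rpf = np.linspace(0.16, 0.9, 10)
        sexes = ["M", "F"] * 5
        donors = donors_from_model(model_id, coeffs, rpf, sexes)
        model = cal.fit_model(donors, model_id)
        np.testing.assert_allclose(model.coefficients, coeffs, atol=1e-7)

    def test_intercept_shift_equivariance(self):
        donors = make_donors(n=60, seed=3)
        m1 = cal.fit_model(donors, 2)
        shifted = [
            DonorRecord(d.donor_id, d.age + 10.0, d.sex, rpf=d.rpf) for d in donors
        ]
        m2 = cal.fit_model(shifted, 2)
        assert m2.coefficients[0] - m1.coefficients[0] == pytest.approx(10.0, abs=1e-8)
        np.testing.assert_allclose(m2.coefficients[1:], m1.coefficients[1:], atol=1e-8)

    def test_single_sex_model3_rejected(self):
        donors = make_donors(n=40, seed=4, male_fraction=1.0)
        with pytest.raises(ValueError, match="both sexes"):
            cal.fit_model(donors, 3)

    def test_missing_rpf_rejected(self):
        donors = [DonorRecord("d1", 50.0, "M"), DonorRecord("d2", 60.0, "F")]
        with pytest.raises(ValueError, match="without rpf"):
            cal.fit_model(donors, 1)


class TestCrossValidate:
    def test_zero_noise_perfect_model(self):
        donors = make_donors(n=80, seed=6, age_noise_sd=0.0)
        m = cal.cross_validate(donors, 2, repeats=5, seed=0)
        assert m.rmse < 1e-6
        assert m.r2 > 1 - 1e-10

    def test_rmse_approaches_noise_sd(self):
        """Known-noise oracle: CV RMSE ~ sigma * sqrt(1 + p/n_train)."""
        sigma = 5.0
        donors = make_donors(n=600, seed=7, age_noise_sd=sigma)
        m = cal.cross_validate(donors, 2, repeats=10, seed=1)
        expected = sigma * np.sqrt(1 + 3 / 540)
        assert m.rmse == pytest.approx(expected, rel=0.08)

    def test_seed_stability_of_mean(self):
        donors = make_donors(n=132, seed=8)
        a = cal.cross_validate(donors, 2, repeats=50, seed=1)
        b = cal.cross_validate(donors, 2, repeats=50, seed=2)
        assert a.per_repeat_rmse != b.per_repeat_rmse
        se = np.std(a.per_repeat_rmse, ddof=1) / np.sqrt(len(a.per_repeat_rmse))
        assert abs(a.rmse - b.rmse) < 4 * se

    def test_cv_rmse_not_below_training_rmse(self):
        donors = make_donors(n=132, seed=9)
        for model_id in (1, 2, 3, 4):
            model = cal.fit_model(donors, model_id)
            n, p = model.n, len(model.terms)
            train_rmse = model.residual_sd * np.sqrt(model.df / n)
            m = cal.cross_validate(donors, model_id, repeats=20, seed=3)
            assert m.rmse >= train_rmse - 1e-9

    def test_too_many_folds_rejected(self):
        donors = make_donors(n=8, seed=10)
        with pytest.raises(ValueError, match="folds exceed"):
            cal.cross_validate(donors, 1, k=10)


class TestSelectModel:
    def metric(self, model_id, rmse, r2):
        return cal.CVMetrics(model_id, rmse, r2, [rmse], [r2], 10, 1, 0)

    def test_lowest_rmse_wins(self):
        ms = [self.metric(1, 12.1, 0.70), self.metric(2, 11.3, 0.74),
              self.metric(3, 11.4, 0.74), self.metric(4, 12.0, 0.70)]
        assert cal.select_model(ms) == 2

    def test_tie_broken_by_r2(self):
        ms = [self.metric(i + 1, 11.0, r2) for i, r2 in enumerate([0.7, 0.74, 0.7, 0.7])]
        assert cal.select_model(ms) == 2

    def test_full_tie_prefers_lower_id(self):
        ms = [self.metric(i, 11.0, 0.7) for i in (4, 2, 3)]
        assert cal.select_model(ms) == 2

    def test_single_candidate_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            cal.select_model([self.metric(1, 11.0, 0.7)])


class TestPredict:
    def test_reference_quadratic_at_half(self):
        model = cal.reference_model(2)
        assert cal.predict_age(model, 0.5) == pytest.approx(38.20, abs=1e-10)

    def test_reference_line_at_zero_gives_intercept(self):
        model = cal.reference_model(1)
        assert cal.predict_age(model, 0.0) == pytest.approx(108.4)

    def test_high_ratio_clamped_to_small_positive(self):
        model = cal.reference_model(2)
        age = cal.predict_age(model, 0.9)
        assert 0.0 <= age < 1.0

    def test_sex_required_for_sex_models(self):
        model = cal.reference_model(3)
        with pytest.raises(ValueError, match="sex"):
            cal.predict_age(model, 0.5)
        assert cal.predict_age(model, 0.5, sex=1) > 0


class TestPredictionInterval:
    def test_published_bounds_reproduced(self):
        """Reproduction mode matches the published 50/80/95% table rows."""
        model = cal.reference_model()
        published = {
            (0.3, 0.50): (61.4, 76.6),
            (0.3, 0.80): (54.5, 83.5),
            (0.3, 0.95): (46.7, 91.3),
            (0.5, 0.50): (30.6, 45.9),
            (0.5, 0.80): (23.7, 52.8),
            (0.5, 0.95): (15.9, 60.6),
        }
        for (r, level), (lo, hi) in published.items():
            pi = cal.prediction_interval(model, r, level, leverage_mode="none")
            assert pi.lower == pytest.approx(lo, abs=0.15)
            assert pi.upper == pytest.approx(hi, abs=0.15)

    def test_lower_bound_clamped_at_zero(self):
        model = cal.reference_model()
        pi = cal.prediction_interval(model, 0.7, 0.95, leverage_mode="none")
        assert pi.lower == 0.0
        assert pi.upper == pytest.approx(37.9, abs=0.15)

    def test_nesting_across_levels(self, calibration_donors):
        model = cal.fit_model(calibration_donors, 2)
        for r in (0.2, 0.4, 0.6, 0.8):
            p50 = cal.prediction_interval(model, r, 0.50)
            p80 = cal.prediction_interval(model, r, 0.80)
            p95 = cal.prediction_interval(model, r, 0.95)
            assert p95.lower <= p80.lower <= p50.lower
            assert p50.upper <= p80.upper <= p95.upper
            assert p50.lower <= p50.point <= p50.upper

    def test_leverage_widens_interval(self, calibration_donors):
        model = cal.fit_model(calibration_donors, 2)
        with_h = cal.prediction_interval(model, 0.5, 0.95, leverage_mode="full")
        without = cal.prediction_interval(model, 0.5, 0.95, leverage_mode="none")
        assert with_h.upper - with_h.lower > without.upper - without.lower

    def test_reproduction_model_requires_zero_leverage(self):
        model = cal.reference_model()
        with pytest.raises(ValueError, match="design moments"):
            cal.prediction_interval(model, 0.5, 0.95, leverage_mode="full")

    def test_empirical_coverage_of_95_interval(self):
        """Marginal coverage of the 95% interval on fresh donors."""
        hits = 0
        total = 0
        for seed in range(3):
            train = make_donors(n=132, seed=100 + seed)
            model = cal.fit_model(train, 2)
            fresh = make_donors(n=2000, seed=200 + seed)
            for d in fresh:
                pi = cal.prediction_interval(model, d.rpf, 0.95, leverage_mode="full")
                raw_point = cal.linear_predictor(model, d.rpf)
                half = pi.upper - raw_point
                # coverage concerns the unclamped probability statement
                hits += raw_point - half <= d.age <= raw_point + half
                total += 1
        assert hits / total == pytest.approx(0.95, abs=0.02)


class TestPredictionTable:
    def test_shape_and_rounding(self):
        model = cal.reference_model()
        t = cal.prediction_table(model, [0.3, 0.4, 0.5, 0.6, 0.7],
                                 leverage_mode="none")
        assert list(t["rpf"]) == [0.3, 0.4, 0.5, 0.6, 0.7]
        assert set(t.columns) == {
            "rpf", "lower_50", "upper_50", "lower_80", "upper_80",
            "lower_95", "upper_95",
        }
        assert t.loc[t.rpf == 0.5, "lower_50"].item() == pytest.approx(30.6, abs=0.15)

    def test_empty_grid_gives_empty_table(self):
        t = cal.prediction_table(cal.reference_model(), [], leverage_mode="none")
        assert len(t) == 0

    def test_constant_width_without_leverage(self):
        t = cal.prediction_table(
            cal.reference_model(), [0.3, 0.5, 0.7], levels=(0.80,),
            leverage_mode="none", decimals=6,
        )
        widths = t["upper_80"] - t["lower_80"]
        # the 0.7 row is clamped at 0; unclamped rows share one width
        assert widths.iloc[0] == pytest.approx(widths.iloc[1], abs=1e-6)


class TestCompareSex:
    def test_null_cohorts_rarely_significant(self):
        flags = [
            cal.compare_sex(make_donors(n=132, seed=300 + s)).significant
            for s in range(30)
        ]
        assert np.mean(flags) <= 0.10

    def test_strong_sex_effect_detected(self):
        rng = np.random.default_rng(0)
        detected = 0
        for s in range(10):
            donors = make_donors(n=132, seed=400 + s)
            shifted = [
                DonorRecord(d.donor_id, d.age + 20.0 * d.sex_code, d.sex, rpf=d.rpf)
                for d in donors
            ]
            detected += cal.compare_sex(shifted).significant
        assert detected == 10

    def test_single_sex_rejected(self):
        donors = make_donors(n=40, seed=12, male_fraction=1.0)
        with pytest.raises(ValueError, match="both sexes"):
            cal.compare_sex(donors)
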