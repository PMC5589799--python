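"""Age-trend fitting, error decomposition, artifact odds, p-values, FDR."""

import numpy as np
import pytest
from scipy import stats as sps

import morphonorm as mn
from morphonorm import normative as nm


class TestFitAgeTrend:
    def test_constant_values_give_order_zero(self):
        ages = np.linspace(10, 70, 40)
        fit = nm.fit_age_trend(ages, np.full(40, 3.7))
        assert fit.order == 0
        assert fit.coefficients[0] == pytest.approx(3.7)
        assert fit.population_sd == pytest.approx(0.0, abs=1e-10)

    def test_linear_slope_recovery(self):
        rng = np.random.default_rng(42)
        ages = rng.uniform(7, 79, 300)
        values = 2.0 + 0.1 * ages + rng.standard_normal(300)
        fit = nm.fit_age_trend(ages, values)
        slope = float(fit.predict(50.0)) - float(fit.predict(49.0))
        assert slope == pytest.approx(0.1, abs=0.02)
        assert fit.population_sd == pytest.approx(1.0, abs=0.15)

    def test_quadratic_order_selected_in_most_fits(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            ages = rng.uniform(7, 79, 250)
            x = (ages - 43.0) / 10.0
            values = 5.0 + 0.5 * x - 0.3 * x**2 + 0.5 * rng.standard_normal(250)
            fit = nm.fit_age_trend(ages, values)
            hits += fit.order == 2
        assert hits >= 95

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            nm.fit_age_trend([10.0, 20.0, 30.0], [1.0, 2.0, 3.0], max_order=3)


class TestMeasurementError:
    def test_identical_repeats_give_zero(self):
        assert nm.estimate_measurement_error(np.zeros(10)) == 0.0

    def test_alternating_difference_gives_d_over_sqrt2(self):
        d = 0.8
        diffs = np.array([d, -d, d, -d, d, -d])
        assert nm.estimate_measurement_error(diffs) == pytest.approx(d / np.sqrt(2))

    def test_no_pairs_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="no repeat pairs"):
            assert nm.estimate_measurement_error(np.empty(0)) == 0.0

    def test_simulation_recovery_within_25_percent(self):
        rng = np.random.default_rng(5)
        sigma_m = 0.5
        diffs = rng.normal(0, np.sqrt(2) * sigma_m, size=30)
        estimate = nm.estimate_measurement_error(diffs)
        assert abs(estimate - sigma_m) / sigma_m < 0.25


class TestArtifactOdds:
    def test_clean_gaussian_sample(self):
        rng = np.random.default_rng(2)
        p_art, odds = nm.estimate_artifact_odds(rng.standard_normal(322))
        assert p_art < 0.01
        assert odds > 100

    def test_ten_percent_gross_outliers(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal(300)
        values[:30] += np.where(rng.random(30) < 0.5, -1, 1) * rng.uniform(8, 15, 30)
        p_art, odds = nm.estimate_artifact_odds(values)
        assert 0.06 < p_art < 0.14
        assert 5 < odds < 16

    def test_odds_always_positive_and_finite(self):
        for values in (np.zeros(25), np.arange(25.0), np.full(25, 1e9)):
            p_art, odds = nm.estimate_artifact_odds(values)
            assert 0 < p_art < 1
            assert 0 < odds < np.inf


def _plain_model(pop_sd=1.0, meas_sd=0.0, df=None):
    return nm.FeatureModel(
        coefficients=np.zeros(4), age_center=40.0, age_scale=15.0,
        population_sd=pop_sd, measurement_sd=meas_sd, order=0, df=df,
    )


class TestAbnormalityP:
    def test_zero_residual(self):
        sign, p = nm.abnormality_p(0.0, 40.0, _plain_model())
        assert sign == 0 and p == 1.0

    def test_gaussian_quantile_identity(self):
        # z = 2.5758... is the two-sided 1% Gaussian point
        sign, p = nm.abnormality_p(2.5758293035489004, 40.0, _plain_model())
        assert sign == 1
        assert p == pytest.approx(0.01, rel=1e-6)

    def test_measurement_error_widens_the_null(self):
        _, p_narrow = nm.abnormality_p(2.0, 40.0, _plain_model(1.0, 0.0))
        _, p_wide = nm.abnormality_p(2.0, 40.0, _plain_model(1.0, 1.0))
        assert p_wide > p_narrow

    def test_monotone_in_magnitude_and_sign_symmetric(self):
        fm = _plain_model(df=200.0)
        _, p1 = nm.abnormality_p(1.0, 40.0, fm)
        _, p2 = nm.abnormality_p(2.0, 40.0, fm)
        sign_neg, p_neg = nm.abnormality_p(-2.0, 40.0, fm)
        assert p2 < p1
        assert p_neg == pytest.approx(p2)
        assert sign_neg == -1

    def test_null_p_values_are_uniform(self):
        """End-to-end micro-pipeline: fit one feature on 300 controls and
        score 2000 new null subjects; the p distribution must be uniform
        (KS p > 0.01)."""
        rng = np.random.default_rng(8)
        ages = rng.uniform(7, 79, 300)
        values = 4.0 - 0.02 * ages + 0.6 * rng.standard_normal(300)
        fit = nm.fit_age_trend(ages, values)
        center, scale = ages.mean(), ages.std()
        t = (ages - center) / scale
        V = np.vander(t, fit.order + 1, increasing=True)
        gram_inv = np.linalg.inv(V.T @ V)
        coeffs_scaled = np.zeros(4)
        poly = np.polynomial.Polynomial(fit.coefficients)(
            np.polynomial.Polynomial([center, scale])
        )
        coeffs_scaled[: len(poly.coef)] = poly.coef
        fm = nm.FeatureModel(
            coefficients=coeffs_scaled, age_center=center, age_scale=scale,
            population_sd=fit.population_sd, measurement_sd=0.0, order=fit.order,
            df=float(fit.df), gram_inv=gram_inv,
        )
        new_ages = rng.uniform(7, 79, 2000)
        new_values = 4.0 - 0.02 * new_ages + 0.6 * rng.standard_normal(2000)
        ps = np.array([nm.abnormality_p(v, a, fm)[1] for v, a in zip(new_values, new_ages)])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_four_sigma_shift_detection_power(self):
        """A shift of 4 null widths is flagged at p < 0.01 with the
        theoretical power Phi(4 - 2.576) ~ 0.92 (a 4-sigma effect observed
        through 1-sigma noise is *not* certain to cross the 2.58-sigma
        threshold)."""
        rng = np.random.default_rng(9)
        fm = _plain_model(1.0, 0.0, df=300.0)
        shifted = 4.0 + rng.standard_normal(2000)
        flags = [nm.abnormality_p(v, 40.0, fm)[1] < 0.01 for v in shifted]
        power = np.mean(flags)
        assert power == pytest.approx(sps.norm.cdf(4.0 - 2.5758), abs=0.03)
        assert power >= 0.85


class TestFdrFlag:
    def test_all_small_p_flagged(self):
        flags = nm.fdr_flag(np.full(2976, 0.005), q=0.01)
        assert flags.all()

    def test_single_p_above_q_not_flagged(self):
        assert not nm.fdr_flag(np.array([0.02]), q=0.01).any()

    def test_matches_brute_force_definition_on_random_sets(self):
        """BH step-up oracle: sort p, find the largest k with
        p_(k) <= q k / m, flag the k smallest."""
        rng = np.random.default_rng(10)
        for _ in range(1000):
            m = rng.integers(1, 120)
            p = rng.uniform(1e-6, 1.0, size=m) ** rng.uniform(0.5, 3.0)
            flags = nm.fdr_flag(p, q=0.01)
            order = np.argsort(p)
            below = np.nonzero(np.sort(p) <= 0.01 * (np.arange(1, m + 1)) / m)[0]
            expected = np.zeros(m, dtype=bool)
            if below.size:
                expected[order[: below[-1] + 1]] = True
            np.testing.assert_array_equal(flags, expected)

    def test_fdr_flags_subset_of_uncorrected(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, 2976) ** 2
        fdr = nm.fdr_flag(p, q=0.01)
        assert not (fdr & ~(p < 0.01)).any()

    def test_empty_input(self):
        assert nm.fdr_flag([]).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            nm.fdr_flag([0.0, 0.5])


class TestBuiltModel:
    def test_trend_and_error_recovery_from_synthetic_cohort(self, small_model, small_cfg):
        """The fitted model recovers the generator's between-subject and
        measurement SDs for a normalized, trend-free feature class."""
        pop = mn.SyntheticPopulation(small_cfg)
        tab = small_model.tables["normalized"]
        fids = [fid for fid in tab.index if fid.endswith("|thickness|left")]
        idx = [pop.index[f] for f in fids]
        fitted_width = np.hypot(
            tab.loc[fids, "population_sd"], tab.loc[fids, "measurement_sd"]
        ).to_numpy()
        truth = pop.null_width[idx]
        ratio = fitted_width / truth
        assert 0.9 < np.median(ratio) < 1.1
        meas_ratio = tab.loc[fids, "measurement_sd"].to_numpy() / (
            pop.sigma_b[idx] * small_cfg.measurement_frac
        )
        assert 0.75 < np.median(meas_ratio) < 1.25

    def test_json_round_trip_scores_identically(self, small_model, small_cfg, tmp_path):
        nulls, _ = mn.generate_controls(
            mn.GeneratorConfig(seed=77, n_controls=3, n_repeat_pairs=0, artifact_rate=0.0)
        )
        before = small_model.score_frame(nulls)[0]
        path = tmp_path / "model.json"
        small_model.to_json(path)
        back = mn.NormativeModel.from_json(path)
        after = back.score_frame(nulls)[0]
        np.testing.assert_allclose(
            before.table["p_normalized"].to_numpy(dtype=float),
            after.table["p_normalized"].to_numpy(dtype=float),
            rtol=1e-12,
        )

    def test_extrapolation_flagged(self, small_model):
        frame, _ = mn.generate_controls(
            mn.GeneratorConfig(seed=78, n_controls=1, n_repeat_pairs=0, artifact_rate=0.0)
        )
        frame.loc[0, "age"] = small_model.age_max + 5.0
        profile = small_model.score_frame(frame)[0]
        assert profile.extrapolated

    def test_fdr_implies_uncorrected_flag(self, small_model, small_cfg):
        patients, _ = mn.generate_patients(small_cfg, "MTLE-HS-left", n=3)
        for profile in small_model.score_frame(patients):
            flags = profile.flags("normalized")
            p = profile.p_values("normalized")
            assert (p[flags == "fdr"] < small_model.alpha).all()
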