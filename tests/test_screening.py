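"""OCR computation, class models, threshold classification, error rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from seednmr.screening import (
    DIPLOID,
    HAPLOID,
    ClassGaussian,
    ClassModel,
    GaussianThresholdScreen,
    accuracy_from_counts,
    classify,
    compare_replicates,
    compute_ocr,
    empirical_error_rates,
    fit_class_gaussians,
    fit_mixture,
    model_error_rates,
    ocr_vs_oil_only,
    separability,
)

FIELD_MODEL = ClassModel(
    haploid_ocr=ClassGaussian(3.6, 0.47),
    diploid_ocr=ClassGaussian(5.5, 0.52),
    haploid_weight=ClassGaussian(0.40, 0.049),
    diploid_weight=ClassGaussian(0.43, 0.035),
)


def simulate_field_ocr(n=1260, seed=20160725, haploid_fraction=0.5):
    rng = np.random.default_rng(seed)
    n_h = int(round(n * haploid_fraction))
    ocr = np.concatenate(
        [rng.normal(3.6, 0.47, n_h), rng.normal(5.5, 0.52, n - n_h)]
    )
    labels = np.array([HAPLOID] * n_h + [DIPLOID] * (n - n_h))
    return pd.DataFrame({"true_class": labels, "ocr_pct": ocr})


class TestComputeOcr:
    def test_reference_kernel(self):
        """28 mg of oil in a 0.42 g kernel is the 6.7% stability reference."""
        assert compute_ocr(28.0, 0.42) == pytest.approx(6.667, abs=1e-3)
        assert round(compute_ocr(28.0, 0.42), 1) == 6.7

    def test_zero_oil(self):
        assert compute_ocr(0.0, 0.3) == 0.0

    @given(a=st.floats(0.1, 100), m=st.floats(0.1, 1.0), c=st.floats(0.1, 10))
    def test_scale_invariance(self, a, m, c):
        assert compute_ocr(c * a, c * m) == pytest.approx(compute_ocr(a, m), rel=1e-9)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            compute_ocr(10.0, 0.0)


class TestClassGaussianFit:
    def test_field_population_recovery(self):
        df = simulate_field_ocr()
        model = fit_class_gaussians(df)
        assert model.haploid_ocr.mean == pytest.approx(3.6, abs=0.05)
        assert model.diploid_ocr.mean == pytest.approx(5.5, abs=0.05)
        assert model.haploid_fraction == pytest.approx(0.5, abs=1e-9)

    def test_degenerate_class_rejected(self):
        df = pd.DataFrame(
            {"true_class": [HAPLOID, HAPLOID, DIPLOID, DIPLOID],
             "ocr_pct": [3.6, 3.6, 5.5, 5.6]}
        )
        with pytest.raises(ValueError, match="degenerate"):
            fit_class_gaussians(df)

    def test_missing_class_rejected(self):
        df = pd.DataFrame({"true_class": [HAPLOID] * 5, "ocr_pct": range(5)})
        with pytest.raises(ValueError):
            fit_class_gaussians(df)

    def test_shuffle_invariance(self):
        df = simulate_field_ocr(n=200)
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        a, b = fit_class_gaussians(df), fit_class_gaussians(shuffled)
        assert a.haploid_ocr.mean == pytest.approx(b.haploid_ocr.mean, rel=1e-12)
        assert a.diploid_ocr.sd == pytest.approx(b.diploid_ocr.sd, rel=1e-12)


class TestMixtureFit:
    def test_unlabelled_field_population(self):
        df = simulate_field_ocr()
        model = fit_mixture(df["ocr_pct"].to_numpy(), seed=0)
        assert model.converged
        assert model.haploid_ocr.mean == pytest.approx(3.6, abs=0.1)
        assert model.diploid_ocr.mean == pytest.approx(5.5, abs=0.1)

    def test_near_degenerate_spikes(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(3.6, 0.01, 500), rng.normal(5.5, 0.01, 500)])
        model = fit_mixture(x, seed=0)
        assert model.haploid_ocr.mean == pytest.approx(3.6, abs=1e-3)
        assert model.diploid_ocr.mean == pytest.approx(5.5, abs=1e-3)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_mixture(np.full(50, 4.0))

    def test_agrees_with_labelled_fit(self):
        """Hidden-label mixture matches the labelled fit within 3 se."""
        df = simulate_field_ocr()
        labelled = fit_class_gaussians(df)
        blind = fit_mixture(df["ocr_pct"].to_numpy(), seed=0)
        se_h = labelled.haploid_ocr.sd / np.sqrt(630)
        se_d = labelled.diploid_ocr.sd / np.sqrt(630)
        assert abs(blind.haploid_ocr.mean - labelled.haploid_ocr.mean) < 3 * se_h
        assert abs(blind.diploid_ocr.mean - labelled.diploid_ocr.mean) < 3 * se_d


class TestClassify:
    @pytest.mark.parametrize(
        "ocr, expected", [(3.6, HAPLOID), (5.5, DIPLOID), (4.25, DIPLOID)]
    )
    def test_threshold_rule(self, ocr, expected):
        assert classify(ocr, 4.25) == expected

    def test_monotone_in_threshold(self):
        """The set called haploid grows monotonically with the threshold."""
        ocr = np.random.default_rng(0).uniform(2, 7, 500)
        prev = np.zeros(500, dtype=bool)
        for thr in np.linspace(2.0, 7.0, 26):
            cur = classify(ocr, thr) == HAPLOID
            assert np.all(prev <= cur)
            prev = cur


class TestModelErrorRates:
    def test_field_false_negative(self):
        """Diploid N(5.5, 0.52) below 4.25% -> ~0.81% false negatives."""
        rep = model_error_rates(FIELD_MODEL, 4.25)
        assert rep.false_negative_pct == pytest.approx(
            100 * stats.norm.cdf((4.25 - 5.5) / 0.52), rel=1e-12
        )
        assert rep.false_negative_pct == pytest.approx(0.81, abs=0.01)

    def test_monte_carlo_oracle(self):
        """The Phi formula matches a 1e6-draw Monte Carlo within 0.02 pp."""
        rng = np.random.default_rng(9)
        frac = 100 * np.mean(rng.normal(5.5, 0.52, 1_000_000) < 4.25)
        rep = model_error_rates(FIELD_MODEL, 4.25)
        assert rep.false_negative_pct == pytest.approx(frac, abs=0.02)

    def test_extreme_threshold_limits(self):
        low = model_error_rates(FIELD_MODEL, 1e-9)
        assert low.false_negative_pct == pytest.approx(0.0, abs=1e-6)
        assert low.false_positive_pct == pytest.approx(100.0, abs=1e-6)

    def test_additive_total(self):
        rep = model_error_rates(FIELD_MODEL, 4.25)
        assert rep.total_error_pct == pytest.approx(
            rep.false_negative_pct + rep.false_positive_pct
        )


class TestEmpiricalErrorRates:
    def test_perfectly_separated(self):
        df = pd.DataFrame(
            {"true_class": [HAPLOID] * 5 + [DIPLOID] * 5,
             "ocr_pct": [3.0] * 5 + [6.0] * 5}
        )
        rep = empirical_error_rates(df, 4.25)
        assert rep.total_error_pct == 0.0
        assert rep.accuracy_pct == 100.0

    def test_single_error_in_hundred(self):
        df = pd.DataFrame(
            {"true_class": [HAPLOID] * 99 + [DIPLOID],
             "ocr_pct": [3.0] * 99 + [3.5]}
        )
        rep = empirical_error_rates(df, 4.25)
        assert rep.false_negative_pct == 100.0  # the one diploid was mis-called
        assert rep.weighted_total_error_pct == pytest.approx(1.0)

    def test_counts_conserve_n(self):
        df = simulate_field_ocr(n=1000)
        rep = empirical_error_rates(df, 4.25)
        assert sum(rep.counts.values()) == 1000

    def test_matches_model_rates_at_large_n(self):
        """Empirical rates agree with the analytic tails within MC error."""
        n = 10_000
        df = simulate_field_ocr(n=n, seed=5)
        emp = empirical_error_rates(df, 4.25)
        mod = model_error_rates(FIELD_MODEL, 4.25)
        for emp_v, mod_v in [
            (emp.false_negative_pct, mod.false_negative_pct),
            (emp.false_positive_pct, mod.false_positive_pct),
        ]:
            p = mod_v / 100
            mc_sd = 100 * np.sqrt(p * (1 - p) / (n / 2))
            assert abs(emp_v - mod_v) < 3 * mc_sd


class TestAccuracyFromCounts:
    @pytest.mark.parametrize(
        "identified, true_positive, expected",
        [
            (321, 308, 95.95),
            (315, 299, 94.92),
            (266, 237, 89.10),
            (303, 279, 92.08),
            (287, 274, 95.47),
            (310, 290, 93.55),
            (1802, 1687, 93.62),
            (100, 100, 100.00),
        ],
    )
    def test_cross_accuracies(self, identified, true_positive, expected):
        assert accuracy_from_counts(identified, true_positive) == expected

    @pytest.mark.parametrize("identified, tp", [(0, 0), (10, 11), (10, -1)])
    def test_invalid_counts_rejected(self, identified, tp):
        with pytest.raises(ValueError):
            accuracy_from_counts(identified, tp)


class TestSeparability:
    def test_ocr_classes_separate(self):
        res = separability(FIELD_MODEL, "ocr")
        assert res.mean_difference == pytest.approx(1.9)
        assert res.half_width_sum == pytest.approx(0.495)
        assert round(res.half_width_sum, 1) == 0.5
        assert res.separable

    def test_weight_classes_overlap(self):
        res = separability(FIELD_MODEL, "weight")
        assert res.mean_difference == pytest.approx(0.03)
        assert res.half_width_sum == pytest.approx(0.042)
        assert round(res.half_width_sum, 2) == 0.04
        assert not res.separable

    def test_identical_classes_not_separable(self):
        model = ClassModel(ClassGaussian(3.6, 0.5), ClassGaussian(3.6 + 1e-9, 0.5))
        res = separability(model, "ocr")
        assert res.mean_difference == pytest.approx(0.0, abs=1e-6)
        assert not res.separable


class TestOcrVsOilOnly:
    @staticmethod
    def _population(n=4000, seed=11, constant_weight=False):
        rng = np.random.default_rng(seed)
        n_h = n // 2
        ocr = np.concatenate([rng.normal(3.6, 0.47, n_h), rng.normal(5.5, 0.52, n_h)])
        if constant_weight:
            mass = np.full(n, 0.42)
        else:
            mass = np.concatenate(
                [rng.normal(0.40, 0.049, n_h), rng.normal(0.43, 0.035, n_h)]
            )
        return pd.DataFrame(
            {
                "true_class": [HAPLOID] * n_h + [DIPLOID] * n_h,
                "ocr_pct": ocr,
                "mass_g": mass,
                "oil_mass_mg": ocr * mass * 10.0,
            }
        )

    def test_constant_weight_makes_rules_identical(self):
        df = self._population(constant_weight=True)
        res = ocr_vs_oil_only(df, oil_threshold_mg=4.25 * 0.42 * 10, ocr_threshold_pct=4.25)
        assert res["ocr_rule"] == res["oil_only_rule"]

    def test_ocr_beats_best_oil_only_threshold(self):
        """Weight normalisation must beat even the optimal oil-mass cut."""
        df = self._population()
        ocr_err = ocr_vs_oil_only(df, 18.0, 4.25)["ocr_rule"]["total_error_pct"]
        best_oil = min(
            ocr_vs_oil_only(df, thr, 4.25)["oil_only_rule"]["total_error_pct"]
            for thr in np.arange(10.0, 26.0, 0.25)
        )
        assert ocr_err < best_oil

    def test_missing_class_rejected(self):
        df = self._population().query("true_class == 'diploid'")
        with pytest.raises(ValueError):
            ocr_vs_oil_only(df, 18.0)


class TestCompareReplicates:
    def test_identical_series(self):
        res = compare_replicates([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_diff == 0.0
        assert res.correlation == pytest.approx(1.0)

    def test_constant_shift(self):
        y1 = np.array([5.1, 5.3, 5.7, 6.0])
        res = compare_replicates(y1 + 0.2, y1)
        assert res.mean_diff == pytest.approx(0.2)
        assert res.correlation == pytest.approx(1.0)

    def test_arithmetic_oracle(self):
        """t = mean/(sd/sqrt(n)) recomputed directly on constructed pairs."""
        rng = np.random.default_rng(7)
        y2 = rng.normal(6.0, 0.5, 10)
        d = rng.normal(-0.02, 0.122, 10)
        y1 = y2 + d
        res = compare_replicates(y1, y2)
        assert res.t_statistic == pytest.approx(
            d.mean() / (d.std(ddof=1) / np.sqrt(10)), rel=1e-12
        )
        assert res.df == 9
        # cross-check against the standard paired t-test
        t, p = stats.ttest_rel(y1, y2)
        assert res.t_statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_replicates([1, 2], [1, 2, 3])


def test_threshold_screen_estimator():
    df = simulate_field_ocr(n=400)
    est = GaussianThresholdScreen(threshold_pct=4.25)
    est.fit(df["ocr_pct"], df["true_class"])
    pred = est.predict([3.0, 6.0])
    assert list(pred) == [HAPLOID, DIPLOID]
    assert est.model_.haploid_ocr.mean < est.model_.diploid_ocr.mean
    assert est.get_params() == {"threshold_pct": 4.25}
    rep = est.error_rates()
    assert 0 <= rep.false_negative_pct <= 100
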