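"""Nonlinear fitting, goodness of fit, and the MSR-first model selection rule."""

import numpy as np
import pandas as pd
import pytest

from lizardgrowth import (
    GrowthRateModel,
    ModelFamily,
    ModelScore,
    NonIdentifiableError,
    compare_models,
    fit_model,
    goodness,
    gr_rate,
    simulate_growth_intervals,
)

FAMILIES = list(ModelFamily)


def intervals_frame(l_ref, gr):
    return pd.DataFrame({"l_ref_mm": l_ref, "gr_mm_per_day": gr})


def linear_lsq_oracle(family, l, gr):
    """Independent closed-form least squares in the transformed predictors."""
    l = np.asarray(l)
    gr = np.asarray(gr)
    if family is ModelFamily.VON_BERTALANFFY:
        X = np.column_stack([np.ones_like(l), l])
        c, s = np.linalg.lstsq(X, gr, rcond=None)[0]
        return -c / s, -s
    if family is ModelFamily.LOGISTIC_BY_LENGTH:
        X = np.column_stack([l, l**2])
        b1, b2 = np.linalg.lstsq(X, gr, rcond=None)[0]
        return -b1 / b2, b1
    X = np.column_stack([l, l**4])
    b1, b2 = np.linalg.lstsq(X, gr, rcond=None)[0]
    return float(np.cbrt(-b1 / b2)), 3.0 * b1


class TestGoodness:
    def test_perfect_prediction(self):
        msr, r2 = goodness([0.02, 0.05, 0.08], [0.02, 0.05, 0.08])
        assert msr == 0.0 and r2 == 1.0

    def test_mean_prediction_gives_zero_r2(self):
        obs = [0.02, 0.05, 0.08]
        msr, r2 = goodness(obs, [np.mean(obs)] * 3, n_params=1)
        assert r2 == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_example(self):
        msr, r2 = goodness([0.02, 0.05, 0.08], [0.03, 0.05, 0.07], n_params=2)
        assert msr == pytest.approx(2e-4, rel=1e-12)
        assert r2 == pytest.approx(1 - 2e-4 / 1.8e-3, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(NonIdentifiableError):
            goodness([0.05, 0.05, 0.05], [0.04, 0.05, 0.06])


class TestFit:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_exact_recovery_on_noiseless_data(self, family):
        a1, r = 46.46, 0.0053
        l = np.linspace(23.0, 44.0, 40)
        data = intervals_frame(l, gr_rate(family, l, (a1, r)))
        res = fit_model(data, family)
        assert res.converged
        assert res.a1 == pytest.approx(a1, abs=1e-6)
        assert res.r == pytest.approx(r, abs=1e-9)
        assert res.msr == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_matches_linear_least_squares_oracle(self, family, rng):
        """The nonlinear optimum must coincide with the exact solution of the
        family's linear reparameterisation whenever that solution is admissible."""
        a1, r = 50.0, 0.004
        for _ in range(10):
            l = rng.uniform(23.0, 47.0, size=120)
            gr = gr_rate(family, l, (a1, r)) + rng.normal(0.0, 0.01, size=120)
            a1_lin, r_lin = linear_lsq_oracle(family, l, gr)
            if not (a1_lin > 0 and r_lin > 0):
                continue
            res = fit_model(intervals_frame(l, gr), family)
            assert res.a1 == pytest.approx(a1_lin, abs=1e-6)
            assert res.r == pytest.approx(r_lin, abs=1e-9)

    def test_von_bertalanffy_equals_simple_linear_regression(self, rng):
        # VB differential form is an ordinary straight line gr = c - r*l
        l = rng.uniform(25.0, 45.0, size=80)
        gr = 0.09 - 0.0018 * l + rng.normal(0, 0.005, size=80)
        slope, intercept = np.polyfit(l, gr, 1)
        res = fit_model(intervals_frame(l, gr), ModelFamily.VON_BERTALANFFY)
        assert res.r == pytest.approx(-slope, abs=1e-9)
        assert res.a1 == pytest.approx(-intercept / slope, abs=1e-6)

    def test_standard_errors_scale_with_noise(self, rng):
        l = rng.uniform(23.0, 44.0, size=300)
        small = gr_rate(ModelFamily.VON_BERTALANFFY, l, (50.0, 0.004)) + rng.normal(0, 0.005, 300)
        large = gr_rate(ModelFamily.VON_BERTALANFFY, l, (50.0, 0.004)) + rng.normal(0, 0.02, 300)
        res_s = fit_model(intervals_frame(l, small), ModelFamily.VON_BERTALANFFY)
        res_l = fit_model(intervals_frame(l, large), ModelFamily.VON_BERTALANFFY)
        assert res_s.params.se_a1 < res_l.params.se_a1
        assert res_s.params.se_r < res_l.params.se_r

    def test_msr_monotone_in_noise(self):
        msrs = []
        for sd in (0.005, 0.01, 0.02, 0.04):
            rng = np.random.default_rng(7)  # common random numbers
            data = simulate_growth_intervals(
                ModelFamily.LOGISTIC_BY_LENGTH, 46.46, 0.0053, n=300, noise_sd=sd, rng=rng
            )
            msrs.append(fit_model(data, ModelFamily.LOGISTIC_BY_LENGTH).msr)
        assert msrs == sorted(msrs)

    def test_constant_predictor_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            GrowthRateModel([0.01, 0.02, 0.03], [30.0, 30.0, 30.0], ModelFamily.VON_BERTALANFFY)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            GrowthRateModel([0.01, 0.02], [30.0, 31.0], ModelFamily.VON_BERTALANFFY)

    def test_summary_renders(self, rng):
        data = simulate_growth_intervals(ModelFamily.VON_BERTALANFFY, 50.0, 0.002, n=50, rng=rng)
        text = fit_model(data, ModelFamily.VON_BERTALANFFY).summary()
        assert "von_bertalanffy" in text and "MSR" in text and "A1" in text


class TestSelection:
    def test_published_male_scores_select_logistic_by_length(self):
        fits = [
            ModelScore(ModelFamily.VON_BERTALANFFY, msr=0.3144, r2=0.3827),
            ModelScore(ModelFamily.LOGISTIC_BY_LENGTH, msr=0.3117, r2=0.3922),
            ModelScore(ModelFamily.LOGISTIC_BY_WEIGHT, msr=0.3123, r2=0.3902),
        ]
        comp = compare_models(fits)
        assert comp.selected is ModelFamily.LOGISTIC_BY_LENGTH
        assert not comp.criteria_conflict

    def test_published_female_scores_select_von_bertalanffy(self):
        fits = [
            ModelScore(ModelFamily.VON_BERTALANFFY, msr=0.3736, r2=0.2353),
            ModelScore(ModelFamily.LOGISTIC_BY_LENGTH, msr=0.3792, r2=0.2026),
            ModelScore(ModelFamily.LOGISTIC_BY_WEIGHT, msr=0.3832, r2=0.1760),
        ]
        assert compare_models(fits).selected is ModelFamily.VON_BERTALANFFY

    def test_msr_tie_broken_by_r2_then_family_order(self):
        fits = [
            ModelScore(ModelFamily.VON_BERTALANFFY, msr=0.3, r2=0.20),
            ModelScore(ModelFamily.LOGISTIC_BY_LENGTH, msr=0.3, r2=0.25),
            ModelScore(ModelFamily.LOGISTIC_BY_WEIGHT, msr=0.4, r2=0.10),
        ]
        assert compare_models(fits).selected is ModelFamily.LOGISTIC_BY_LENGTH
        fits = [
            ModelScore(ModelFamily.LOGISTIC_BY_WEIGHT, msr=0.3, r2=0.2),
            ModelScore(ModelFamily.VON_BERTALANFFY, msr=0.3, r2=0.2),
            ModelScore(ModelFamily.LOGISTIC_BY_LENGTH, msr=0.5, r2=0.1),
        ]
        assert compare_models(fits).selected is ModelFamily.VON_BERTALANFFY

    def test_msr_wins_conflicts_and_records_them(self):
        fits = [
            ModelScore(ModelFamily.VON_BERTALANFFY, msr=0.30, r2=0.20),
            ModelScore(ModelFamily.LOGISTIC_BY_LENGTH, msr=0.31, r2=0.40),
            ModelScore(ModelFamily.LOGISTIC_BY_WEIGHT, msr=0.32, r2=0.30),
        ]
        comp = compare_models(fits)
        assert comp.selected is ModelFamily.VON_BERTALANFFY
        assert comp.criteria_conflict
        assert comp.r2_rank[0] is ModelFamily.LOGISTIC_BY_LENGTH

    def test_unconverged_member_attaches_warning(self):
        fits = [
            ModelScore(ModelFamily.VON_BERTALANFFY, msr=0.3, r2=0.2, converged=False),
            ModelScore(ModelFamily.LOGISTIC_BY_LENGTH, msr=0.4, r2=0.1),
            ModelScore(ModelFamily.LOGISTIC_BY_WEIGHT, msr=0.5, r2=0.05),
        ]
        with pytest.warns(UserWarning):
            comp = compare_models(fits)
        assert comp.warning is not None

    def test_duplicate_family_rejected(self):
        fits = [
            ModelScore(ModelFamily.VON_BERTALANFFY, msr=0.3, r2=0.2),
            ModelScore(ModelFamily.VON_BERTALANFFY, msr=0.4, r2=0.1),
        ]
        with pytest.raises(ValueError):
            compare_models(fits)
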