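import numpy as np
import pandas as pd
import pytest

from idmaft import estimation as est
from idmaft.likelihood import RandomEffectSpec, SubjectArrays, SubjectRecord
from idmaft.simulate import generate, scenario
from idmaft.transitions import TransitionParams, weibull_mean, weibull_median


def _death_only_records(ages, entry=0.0):
    """Subjects observed from `entry` until death (no diagnosis)."""
    return [
        SubjectRecord(
            entry_age=entry, t_left=a, t_right=np.inf, last_age=a,
            delta1=0, delta2=1, x=np.array([1.0]),
        )
        for a in ages
    ]


class TestFitUnivariate:
    def test_exponential_death_ages_recover_scale(self):
        # kappa=1, no censoring/truncation: the MLE scale is the sample mean
        rng = np.random.default_rng(0)
        ages = rng.exponential(10.0, size=2000)
        tp = est.fit_univariate("m0", _death_only_records(ages))
        assert np.exp(tp.beta[0]) == pytest.approx(ages.mean(), rel=0.02)
        assert tp.kappa == pytest.approx(1.0, rel=0.1)

    def test_sharp_weibull_recovery(self):
        rng = np.random.default_rng(1)
        ages = 95.0 * rng.weibull(8.0, size=2000)
        tp = est.fit_univariate("m0", _death_only_records(ages))
        assert np.exp(tp.beta[0]) == pytest.approx(95.0, rel=0.02)
        assert tp.kappa == pytest.approx(8.0, rel=0.1)

    def test_all_censored_triggers_fallback(self):
        records = [
            SubjectRecord(
                entry_age=60.0, t_left=80.0, t_right=np.inf, last_age=80.0,
                delta1=0, delta2=0, x=np.array([1.0]),
            )
            for _ in range(20)
        ]
        with pytest.warns(UserWarning, match="moment-based"):
            tp = est.fit_univariate("m1", records)
        assert tp.kappa > 0


@pytest.fixture(scope="module")
def cohort_fits(small_cohort):
    _, dataset, _ = small_cohort
    arrays = SubjectArrays(dataset)
    fits = {
        s: est.fit(arrays, structure=s, compute_se=(s == "homvar"))
        for s in ("none", "homvar", "hetvar")
    }
    return dataset, fits


@pytest.fixture(scope="module")
def fitted(small_cohort):
    _, dataset, _ = small_cohort
    return est.fit(dataset, structure="homvar")


class TestFit:
    def test_information_criteria_definitions(self, cohort_fits):
        dataset, fits = cohort_fits
        for res in fits.values():
            assert res.aic == pytest.approx(
                -2 * res.loglik + 2 * res.n_free_params
            )
            assert res.bic == pytest.approx(
                -2 * res.loglik + np.log(res.n_subjects) * res.n_free_params
            )
            assert res.n_subjects == len(dataset)

    def test_nested_model_likelihood_ordering(self, cohort_fits):
        _, fits = cohort_fits
        # zero-variance boundary: both RE models contain the fixed model
        assert fits["homvar"].loglik >= fits["none"].loglik - 1e-4
        assert fits["hetvar"].loglik >= fits["none"].loglik - 1e-4
        assert fits["hetvar"].loglik >= fits["homvar"].loglik - 1e-4

    def test_single_replicate_parameter_recovery(self, small_cohort):
        # one n=2400 early-censoring cohort: estimates land near truth
        scen = scenario("E65_L", seed=77)
        dataset, _ = generate(scen)
        res = est.fit(dataset, structure="none", compute_se=False)
        truth = scen.true_params("none")
        for tp_true in truth.transition_params:
            lab = tp_true.label
            assert abs(res[f"b1_{lab}"] - tp_true.beta[1]) < 0.05
        assert abs(res["b0_m0"] - truth.mort0.beta[0]) < 0.05
        assert res.converged

    def test_refit_from_estimate_is_stationary(self, cohort_fits):
        dataset, fits = cohort_fits
        res = fits["homvar"]
        res2 = est.fit(
            dataset, structure="homvar",
            start=res.params_hat, compute_se=False,
        )
        assert abs(res2.loglik - res.loglik) < 1e-5

    def test_standard_errors_positive_where_defined(self, cohort_fits):
        _, fits = cohort_fits
        se = fits["homvar"].se
        finite = np.isfinite(se)
        assert finite[:9].all()  # regression and shape parameters
        assert np.all(se[finite] >= 0)

    def test_summary_frame_shape(self, cohort_fits):
        _, fits = cohort_fits
        summ = fits["hetvar"].summary()
        assert list(summ.columns) == ["estimate", "se", "ci_low", "ci_high"]
        assert set(["si2", "sm02", "sm12", "ci_m1", "cm0_m1"]) <= set(summ.index)


class TestWaldCI:
    def test_standard_normal_quantile(self):
        lo, hi = est.wald_ci(0.0, 1.0, 0.95)
        assert lo == pytest.approx(-1.959964, abs=1e-5)
        assert hi == pytest.approx(1.959964, abs=1e-5)

    def test_zero_se_degenerates(self):
        lo, hi = est.wald_ci(0.42, 0.0)
        assert lo == hi == 0.42

    def test_matches_reported_interval(self):
        # se back-solved from a (-0.02, 0.07) interval around 0.03
        se = (0.07 - (-0.02)) / (2 * 1.959964)
        lo, hi = est.wald_ci(0.025, se)
        assert round(lo, 2) == -0.02 and round(hi, 2) == 0.07


class TestDerivedTables:
    def test_effect_table_af_is_exp_beta(self, fitted):
        table = est.effect_table(fitted, covariate_names=["sex"])
        assert set(table["transition"]) == {"i", "m0", "m1"}
        np.testing.assert_allclose(table["af"], np.exp(table["beta"]))
        np.testing.assert_allclose(table["af_low"], np.exp(table["beta_low"]))
        np.testing.assert_allclose(table["af_high"], np.exp(table["beta_high"]))

    def test_effect_table_hr_af_duality(self, fitted):
        table = est.effect_table(fitted)
        for _, row in table.iterrows():
            kappa = fitted[f"kappa_{row['transition']}"]
            assert row["hr"] * row["af"] ** kappa == pytest.approx(1.0, rel=1e-10)
        assert (table["hr_low"] <= table["hr"]).all()
        assert (table["hr"] <= table["hr_high"]).all()

    def test_profile_summaries_consistency(self, fitted):
        profs = est.profile_summaries(fitted, {"female": [0.0], "male": [1.0]})
        assert len(profs) == 6
        for s in profs:
            kappa = fitted[f"kappa_{s.transition}"]
            ratio = weibull_median(0.0, kappa) / weibull_mean(0.0, kappa)
            assert s.median / s.mean == pytest.approx(ratio, rel=1e-10)
            assert s.mean_low <= s.mean <= s.mean_high
            assert s.median_low <= s.median <= s.median_high

    def test_median_survival_difference_consistency(self, fitted):
        val, lo, hi = est.median_survival_difference(fitted, [0.0])
        profs = est.profile_summaries(fitted, {"female": [0.0]})
        med = {s.transition: s.median for s in profs}
        assert val == pytest.approx(med["m0"] - med["m1"], rel=1e-10)
        assert lo <= val <= hi

    def test_identical_transitions_give_zero_difference(self, fitted):
        clone = est.FitResult(
            structure="none",
            params_hat=fitted.params_hat,
            param_names=fitted.param_names,
            estimates=fitted.estimates.copy(),
            se=fitted.se,
            cov=fitted.cov,
            loglik=0.0, aic=0.0, bic=0.0,
            n_subjects=1, n_free_params=1, converged=True, n_points=2,
            covariate_names=fitted.covariate_names,
        )
        names = clone.param_names
        # copy m0 parameters onto m1
        for stem in ("b0", "b1", "kappa"):
            clone.estimates[names.index(f"{stem}_m1")] = clone.estimates[
                names.index(f"{stem}_m0")
            ]
        val, _, _ = est.median_survival_difference(clone, [0.0])
        assert val == pytest.approx(0.0, abs=1e-12)
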