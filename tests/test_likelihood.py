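import numpy as np
import pytest

from idmaft import transitions as tr
from idmaft.likelihood import (
    ModelParams,
    RandomEffectSpec,
    SubjectArrays,
    SubjectRecord,
    case_of,
    log_contribution,
    marginal_loglik,
    quadrature_grid,
)
from idmaft.transitions import TransitionParams

from conftest import make_subject


@pytest.mark.parametrize(
    "d1,d2,case",
    [(1, 1, "I"), (1, 0, "II"), (0, 1, "III"), (0, 0, "IV")],
)
def test_case_classification(d1, d2, case):
    s = make_subject(delta1=d1, delta2=d2)
    assert case_of(s) == case


def _no_re(inc, m0, m1):
    return ModelParams(inc=inc, mort0=m0, mort1=m1, re=RandomEffectSpec("none"))


class TestLogContribution:
    def test_exponential_case_three_closed_form(self):
        # all-unit exponentials: death observed at 2 after entry at 1 gives
        # log[S_i(2) f_m0(2)] - log[S_i(1) S_m0(1)] = -2 - 2 + 1 + 1 = -2
        unit = lambda lab: TransitionParams(np.array([0.0]), 1.0, lab)
        params = _no_re(unit("i"), unit("m0"), unit("m1"))
        s = SubjectRecord(
            entry_age=1.0, t_left=2.0, t_right=np.inf, last_age=2.0,
            delta1=0, delta2=1, x=np.array([1.0]),
        )
        assert log_contribution(s, params, np.zeros(3)) == pytest.approx(-2.0)

    def test_case_one_termwise_recomputation(self, example_params):
        s = make_subject(entry=58.0, t_left=75.0, t_right=79.0, last=84.0)
        u = np.array([0.05, -0.02, 0.03])
        etas = [
            tr.weibull_scale(s.x, tp, u[k])
            for k, tp in enumerate(example_params.transition_params)
        ]
        kappas = [tp.kappa for tp in example_params.transition_params]
        expected = (
            np.log(
                tr.survival(s.t_left, etas[0], kappas[0])
                - tr.survival(s.t_right, etas[0], kappas[0])
            )
            + np.log(tr.survival(s.t_right, etas[1], kappas[1]))
            + tr.log_density(s.last_age, etas[2], kappas[2])
            - np.log(tr.survival(s.entry_age, etas[0], kappas[0]))
            - np.log(tr.survival(s.entry_age, etas[1], kappas[1]))
            - np.log(tr.survival(s.t_mid, etas[2], kappas[2]))
        )
        got = log_contribution(s, example_params, u)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_case_two_uses_survival_not_density(self, example_params):
        s1 = make_subject(delta2=1)
        s2 = make_subject(delta2=0)
        u = np.zeros(3)
        eta = tr.weibull_scale(s1.x, example_params.mort1)
        k = example_params.mort1.kappa
        diff = log_contribution(s1, example_params, u) - log_contribution(
            s2, example_params, u
        )
        expected = tr.log_density(s1.last_age, eta, k) - np.log(
            tr.survival(s1.last_age, eta, k)
        )
        assert diff == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("delta2", [0, 1])
    def test_truncation_correction_factorizes(self, example_params, delta2):
        # cases III/IV: entry at L just divides by S_i(L) S_m0(L)
        entry = 62.0
        kwargs = dict(t_left=0.0, t_right=np.inf, last=85.0, delta1=0, delta2=delta2)
        s_trunc = make_subject(entry=entry, **kwargs)
        s_birth = make_subject(entry=1e-12, **kwargs)
        u = np.array([0.01, 0.02, -0.01])
        correction = sum(
            np.log(tr.survival(entry, tr.weibull_scale(s_trunc.x, tp, u[k]), tp.kappa))
            for k, tp in enumerate(example_params.transition_params[:2])
        )
        assert log_contribution(s_trunc, example_params, u) == pytest.approx(
            log_contribution(s_birth, example_params, u) - correction, rel=1e-10
        )

    def test_interval_shrinks_to_onset_density(self, example_params):
        # as Tr - Tl -> 0 the interval term [S(Tl)-S(Tr)] / (Tr-Tl)
        # converges to the exact-onset incidence density, so the whole
        # contribution converges to the exact-onset form
        t1, u = 78.0, np.zeros(3)
        x = np.array([1.0, 1.0])
        etas = [tr.weibull_scale(x, tp) for tp in example_params.transition_params]
        kappas = [tp.kappa for tp in example_params.transition_params]
        s0 = make_subject(t_left=t1 - 0.5, t_right=t1 + 0.5, last=85.0)
        exact = (
            tr.log_density(t1, etas[0], kappas[0])
            + np.log(tr.survival(t1, etas[1], kappas[1]))
            + tr.log_density(s0.last_age, etas[2], kappas[2])
            - np.log(tr.survival(s0.entry_age, etas[0], kappas[0]))
            - np.log(tr.survival(s0.entry_age, etas[1], kappas[1]))
            - np.log(tr.survival(t1, etas[2], kappas[2]))
        )
        prev_err = np.inf
        for width in (1.0, 0.1, 0.01, 0.001):
            s = make_subject(
                t_left=t1 - width / 2, t_right=t1 + width / 2, last=85.0
            )
            got = log_contribution(s, example_params, u) - np.log(width)
            err = abs(got - exact)
            assert err < prev_err
            prev_err = err
        assert got == pytest.approx(exact, abs=1e-4)

    def test_empty_interval_returns_neg_inf_with_warning(self, example_params):
        # clamping Tl to the entry age can leave a zero-width interval
        s = make_subject(entry=76.0, t_left=74.0, t_right=76.0, last=85.0)
        with pytest.warns(UserWarning):
            val = log_contribution(s, example_params, np.zeros(3))
        assert val == -np.inf

    def test_entry_after_last_age_rejected(self):
        with pytest.raises(ValueError):
            make_subject(entry=90.0, last=85.0, delta1=0)

    def test_interval_straddling_entry_clamped(self, example_params):
        s_raw = SubjectRecord(
            entry_age=76.0, t_left=74.0, t_right=80.0, last_age=85.0,
            delta1=1, delta2=1, x=np.array([1.0, 0.0]),
        )
        with pytest.warns(UserWarning, match="clamped"):
            arr = SubjectArrays([s_raw])
        assert arr.t_left[0] == 76.0
        assert arr.t_mid[0] == pytest.approx(0.5 * (76.0 + 80.0))


class TestQuadratureGrid:
    def test_degenerate_variance_single_node(self):
        nodes, w = quadrature_grid(RandomEffectSpec("homvar", s2=0.0), 4)
        assert nodes.shape == (1, 3) and np.all(nodes == 0) and w[0] == 1.0

    def test_two_point_standard_normal(self):
        nodes, w = quadrature_grid(RandomEffectSpec("homvar", s2=1.0), 2)
        assert sorted(nodes[:, 0]) == pytest.approx([-1.0, 1.0])
        assert w == pytest.approx([0.5, 0.5])
        # shared effect: identical value in all three positions
        assert np.all(nodes == nodes[:, :1])

    def test_weights_sum_to_one(self):
        re = RandomEffectSpec("hetvar", si2=0.3, sm02=0.2, sm12=0.1, ci_m1=0.05)
        nodes, w = quadrature_grid(re, 3)
        assert nodes.shape == (27, 3)
        assert w.sum() == pytest.approx(1.0, rel=1e-12)

    def test_quadratic_moments_exact(self):
        # a 2-point-per-dimension rule integrates quadratics exactly
        re = RandomEffectSpec("hetvar", si2=0.5, sm02=0.25, sm12=0.75)
        nodes, w = quadrature_grid(re, 2)
        integrand = nodes[:, 0] ** 2 + 2 * nodes[:, 1] ** 2 + nodes[:, 2]
        expected = 0.5 + 2 * 0.25 + 0.0
        assert float(w @ integrand) == pytest.approx(expected, abs=1e-10)

    def test_covariance_reproduced(self):
        re = RandomEffectSpec(
            "hetvar", si2=0.4, sm02=0.3, sm12=0.2, ci_m1=0.1, cm0_m1=-0.05
        )
        nodes, w = quadrature_grid(re, 3)
        emp = (nodes * w[:, None]).T @ nodes
        np.testing.assert_allclose(emp, re.covariance(), atol=1e-10)

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError):
            RandomEffectSpec("hetvar", si2=0.01, sm02=0.01, sm12=0.01, ci_m1=0.5)


class TestMarginalLoglik:
    def test_zero_variance_equals_no_re(self, small_cohort, example_params):
        _, dataset, _ = small_cohort
        none_params = ModelParams(
            example_params.inc,
            example_params.mort0,
            example_params.mort1,
            re=RandomEffectSpec("none"),
        )
        zero_var = ModelParams(
            example_params.inc,
            example_params.mort0,
            example_params.mort1,
            re=RandomEffectSpec("homvar", s2=0.0),
        )
        a = marginal_loglik(dataset, none_params)
        b = marginal_loglik(dataset, zero_var, n_points=8)
        assert b == pytest.approx(a, abs=1e-10)

    def test_duplicating_data_doubles_loglik(self, small_cohort, example_params):
        _, dataset, _ = small_cohort
        sub = dataset.head(50)
        ll1 = marginal_loglik(sub, example_params, n_points=2)
        ll2 = marginal_loglik(
            sub.iloc[np.repeat(np.arange(len(sub)), 2)].reset_index(drop=True),
            example_params,
            n_points=2,
        )
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_permutation_invariance(self, small_cohort, example_params):
        _, dataset, _ = small_cohort
        shuffled = dataset.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert marginal_loglik(shuffled, example_params) == pytest.approx(
            marginal_loglik(dataset, example_params), rel=1e-12
        )

    def test_quadrature_refinement_converges(self, small_cohort, example_params):
        _, dataset, _ = small_cohort
        lls = [
            marginal_loglik(dataset, example_params, n_points=q) for q in (2, 8, 16)
        ]
        assert abs(lls[2] - lls[1]) <= abs(lls[1] - lls[0]) + 1e-12
        assert abs(lls[2] - lls[1]) < 1e-4

    def test_impossible_subject_flagged_by_index(self, example_params):
        good = make_subject()
        bad = make_subject(entry=76.0, t_left=74.0, t_right=76.0, last=85.0)
        with pytest.raises(ValueError, match=r"\[1\]"), pytest.warns(UserWarning):
            marginal_loglik([good, bad], example_params, n_points=2)


def test_model_params_requires_matching_designs():
    with pytest.raises(ValueError):
        ModelParams(
            TransitionParams(np.array([1.0, 2.0]), 1.0, "i"),
            TransitionParams(np.array([1.0]), 1.0, "m0"),
            TransitionParams(np.array([1.0, 2.0]), 1.0, "m1"),
        )
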