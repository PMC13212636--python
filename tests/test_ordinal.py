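import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ctbenefit.design import ModelSpec, Term, build_design_matrix
from ctbenefit.ordinal import (
    ContractError,
    backward_eliminate,
    fit_model,
    fit_proportional_odds,
    likelihood_ratio_test,
    predict_benefit,
    predict_distribution,
    predict_good_outcome,
    summarize_effects,
)
from ctbenefit.simulate import default_hermes_config, generate_cohort, scale_trials
from tests.conftest import tiny_frame


def simulate_ordinal(rng, X, beta, alpha):
    eta = X @ beta
    cum = expit(alpha[None, :] + eta[:, None])
    cum = np.column_stack([cum, np.ones(len(X))])
    return (rng.random(len(X))[:, None] > cum).sum(axis=1)


class TestFit:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 7, 500)
        m = fit_proportional_odds(np.zeros((500, 0)), y)
        emp = np.cumsum(np.bincount(y, minlength=7))[:-1] / 500
        assert np.allclose(m.alpha, logit(emp), atol=1e-8)

    def test_two_category_fit_matches_binary_logistic(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = rng.normal(size=(800, 3))
        y = (rng.random(800) < expit(0.3 + X @ [0.8, -0.5, 0.1])).astype(int)
        # orientation: P(y <= 0) = expit(alpha + x beta) = P(y = 0)
        m = fit_proportional_odds(X, y)
        glm = sm.GLM(1 - y, sm.add_constant(X),
                     family=sm.families.Binomial()).fit(tol=1e-12)
        assert np.max(np.abs(m.beta - glm.params[1:])) < 1e-6
        assert abs(m.alpha[0] - glm.params[0]) < 1e-6

    def test_matches_statsmodels_ordered_model(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(2)
        X = rng.normal(size=(600, 2))
        y = simulate_ordinal(rng, X, np.array([0.6, -0.4]),
                             np.array([-1.5, -0.5, 0.5, 1.5]))
        m = fit_proportional_odds(X, y)
        sm_fit = OrderedModel(pd.Series(y), X, distr="logit").fit(
            method="bfgs", disp=False, gtol=1e-10
        )
        # statsmodels parameterizes P(y<=k) = F(cut_k - x beta)
        assert np.allclose(m.beta, -np.asarray(sm_fit.params)[:2], atol=1e-4)
        assert np.allclose(m.beta_se(), np.asarray(sm_fit.bse)[:2], atol=1e-4)

    def test_equivariance_under_column_scaling(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 2))
        y = simulate_ordinal(rng, X, np.array([0.5, 0.2]),
                             np.array([-1.0, 0.0, 1.0]))
        m1 = fit_proportional_odds(X, y)
        X2 = X.copy()
        X2[:, 0] *= 10.0
        m2 = fit_proportional_odds(X2, y)
        assert m2.beta[0] == pytest.approx(m1.beta[0] / 10.0, rel=1e-6)
        assert m2.loglik == pytest.approx(m1.loglik, abs=1e-8)

    def test_gradient_norm_small_at_optimum(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(300, 3))
        y = simulate_ordinal(rng, X, np.array([0.4, 0.0, -0.2]),
                             np.array([-1.0, 0.5]))
        m = fit_proportional_odds(X, y)
        assert m.grad_norm < 1e-6
        assert m.converged

    def test_evt_coefficient_recovery(self, big_cohort, default_config):
        m = fit_model(big_cohort.data, default_config.true_spec())
        i = m.labels.index("evt")
        assert abs(m.beta[i] - np.log(1.92)) < 0.35  # single draw, wide SE
        # tight recovery for the precisely estimated severity score
        j = m.labels.index("nihss")
        assert abs(m.beta[j] - np.log(0.93)) < 0.02


class TestPredict:
    def _uniform_model(self):
        rng = np.random.default_rng(5)
        y = np.repeat(np.arange(7), 30)
        return fit_proportional_odds(np.zeros((210, 0)), y)

    def test_uniform_distribution(self):
        m = self._uniform_model()
        probs = predict_distribution(m, np.zeros((4, 0)))
        assert np.allclose(probs, 1 / 7, atol=1e-8)

    def test_rows_sum_to_one_and_nonnegative(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 2))
        y = simulate_ordinal(rng, X, np.array([1.0, -1.0]),
                             np.array([-2, -1, 0, 1, 2, 3.0]))
        m = fit_proportional_odds(X, y)
        probs = predict_distribution(m, X)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_good_outcome_equals_first_three_categories(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(150, 1))
        y = simulate_ordinal(rng, X, np.array([0.8]),
                             np.array([-2, -1, 0, 1, 2, 3.0]))
        m = fit_proportional_odds(X, y)
        probs = predict_distribution(m, X)
        assert np.allclose(predict_good_outcome(m, X),
                           probs[:, :3].sum(axis=1), atol=1e-12)

    def test_treatment_odds_ratio_arithmetic(self):
        # eta = ln(1.92), alpha_2 = 0 -> P(good) = expit(0.652) ~ 0.657
        assert expit(np.log(1.92)) == pytest.approx(0.6575, abs=5e-4)

    def test_benefit_zero_without_treatment_effect(self):
        df = tiny_frame(30, seed=8)
        spec = ModelSpec(
            "b",
            [
                Term(kind="treatment", variable="evt"),
                Term(kind="linear", variable="aspects"),
            ],
        )
        m = fit_model(df, spec)
        m.beta[m.labels.index("evt")] = 0.0
        out = predict_benefit(m, df)
        assert np.allclose(out["benefit"], 0.0, atol=1e-12)

    def test_benefit_monotone_in_collateral_with_positive_interaction(self):
        df = tiny_frame(40, seed=9)
        spec = ModelSpec(
            "b",
            [
                Term(kind="treatment", variable="evt"),
                Term(kind="linear", variable="collateral"),
                Term(kind="interaction", variable="evt",
                     with_variable="collateral"),
            ],
        )
        m = fit_model(df, spec)
        m.beta[:] = [np.log(1.9), 0.3, np.log(1.2)]
        probe = df.iloc[[0]].copy()
        benefits = []
        for c in range(4):
            probe["collateral"] = c
            benefits.append(predict_benefit(m, probe)["benefit"].iloc[0])
        assert np.all(np.diff(benefits) >= -1e-12)

    def test_benefit_requires_treatment_term(self):
        df = tiny_frame(30, seed=10)
        m = fit_model(df, ModelSpec("nt", [Term(kind="linear",
                                                variable="aspects")]))
        with pytest.raises(ContractError):
            predict_benefit(m, df)


class TestEliminationAndLRT:
    def test_p_remove_one_removes_nothing(self, complete_cohort,
                                          default_config):
        spec = default_config.true_spec()
        reduced, trace = backward_eliminate(spec, complete_cohort.data,
                                            p_remove=1.0)
        assert trace == []
        assert len(reduced.terms) == len(spec.terms)

    def test_null_predictor_usually_removed_treatment_always_kept(
        self, default_config
    ):
        # old-infarct volume has a generating coefficient of exactly zero
        removed, evt_kept = 0, 0
        reps = 10
        for s in range(reps):
            cfg = scale_trials(default_config, 5000, missing_rate=0.0)
            coh = generate_cohort(cfg, seed=100 + s)
            reduced, trace = backward_eliminate(
                default_config.true_spec(), coh.data, p_remove=0.20
            )
            if "old_infarct_volume" in [t[0] for t in trace]:
                removed += 1
            if any(t.kind == "treatment" for t in reduced.terms):
                evt_kept += 1
        assert evt_kept == reps
        assert removed >= 0.8 * reps

    def test_identical_specs_lrt(self, complete_cohort):
        spec = ModelSpec("s", [Term(kind="linear", variable="aspects")])
        m = fit_model(complete_cohort.data, spec)
        stat, df, p = likelihood_ratio_test(m, m)
        assert stat == 0.0 and p == 1.0

    def test_three_level_categorical_adds_two_df(self, complete_cohort):
        base = ModelSpec("b", [Term(kind="linear", variable="aspects")])
        full = ModelSpec(
            "f",
            [
                Term(kind="linear", variable="aspects"),
                Term(kind="categorical", variable="icac"),
            ],
        )
        mb = fit_model(complete_cohort.data, base)
        mf = fit_model(complete_cohort.data, full)
        _, df, _ = likelihood_ratio_test(mf, mb)
        assert df == 2

    def test_non_nested_rejected(self, complete_cohort):
        a = fit_model(complete_cohort.data,
                      ModelSpec("a", [Term(kind="linear", variable="aspects")]))
        b = fit_model(complete_cohort.data,
                      ModelSpec("b", [Term(kind="linear", variable="nihss")]))
        with pytest.raises(ContractError):
            likelihood_ratio_test(a, b)


class TestSummaries:
    def test_linear_or_and_ci_match_direct_computation(self, complete_cohort):
        spec = ModelSpec("s", [Term(kind="linear", variable="aspects")])
        m = fit_model(complete_cohort.data, spec)
        tab = summarize_effects(m)
        b, se = m.beta[0], m.beta_se()[0]
        row = tab.iloc[0]
        assert row["or"] == pytest.approx(np.exp(b), rel=1e-12)
        assert row["ci_low"] == pytest.approx(np.exp(b - 1.96 * se), rel=1e-3)
        assert row["ci_high"] == pytest.approx(np.exp(b + 1.96 * se), rel=1e-3)

    def test_spline_on_linear_truth_gives_equal_chord_ors(self):
        # generate with a purely linear age effect; fitted spline chords on
        # both sides of the inflection agree
        rng = np.random.default_rng(11)
        n = 20000
        age = rng.uniform(40, 90, n)
        X = age[:, None]
        y = simulate_ordinal(rng, X, np.array([-0.04]),
                             np.array([1.0, 2.0, 3.0]) + 0.04 * 65)
        df = pd.DataFrame({"age": age, "mrs90": y})
        spec = ModelSpec("s", [Term(kind="spline", variable="age",
                                    knots=(50.0, 65.0, 83.0))])
        dm = build_design_matrix(df, spec)
        m = fit_proportional_odds(dm.X, y, labels=dm.labels, spec=spec,
                                  term_of_column=dm.term_of_column)
        tab = summarize_effects(m)
        below, above = tab["or"].to_numpy()
        assert below == pytest.approx(above, abs=0.01)
        assert below == pytest.approx(np.exp(-0.04), abs=0.01)
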