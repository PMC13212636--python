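import numpy as np
import pandas as pd
import pytest

from ctbenefit import load_builtin_spec
from ctbenefit.design import Term
from ctbenefit.simulate import generate_cohort, scale_trials
from ctbenefit.validation import (
    ContractError,
    added_value_analysis,
    compare_models_bootstrap,
    iecv,
    pool_random_effects,
    run_full_analysis,
)


class TestPooling:
    def test_identical_folds_collapse(self):
        pe = pool_random_effects([0.7, 0.7, 0.7], [0.02, 0.02, 0.02])
        assert pe.value == pytest.approx(0.7, abs=1e-12)
        assert pe.tau2 == 0.0

    def test_single_fold(self):
        pe = pool_random_effects([0.7], [0.02])
        assert pe.value == 0.7
        assert pe.ci_low == pytest.approx(0.7 - 1.96 * 0.02)

    def test_two_study_closed_form(self):
        # hand computation: y=(0.70, 0.76), se=(0.02, 0.02)
        # w=2500 each; ybar=0.73; Q=2500*0.0009*2=4.5
        # denom = 5000 - (2*2500^2)/5000 = 2500; tau2=(4.5-1)/2500=0.0014
        # w*=1/(0.0004+0.0014)=555.55..; pooled=0.73
        pe = pool_random_effects([0.70, 0.76], [0.02, 0.02])
        assert pe.value == pytest.approx(0.73, abs=1e-10)
        assert pe.tau2 == pytest.approx(0.0014, abs=1e-10)
        se = np.sqrt(1 / (2 / 0.0018))
        assert pe.ci_high == pytest.approx(0.73 + 1.96 * se, abs=1e-10)

    def test_pooled_within_fold_range(self):
        rng = np.random.default_rng(30)
        vals = rng.uniform(0.6, 0.8, 7)
        ses = rng.uniform(0.01, 0.05, 7)
        pe = pool_random_effects(vals, ses)
        assert vals.min() <= pe.value <= vals.max()

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ContractError):
            pool_random_effects([0.7, 0.8], [0.02, 0.0])


@pytest.fixture(scope="module")
def mid_cohort(default_config):
    return generate_cohort(scale_trials(default_config, 1391,
                                        missing_rate=0.0), seed=77)


class TestIECV:
    def test_fold_count_equals_trial_count(self, mid_cohort):
        res = iecv(mid_cohort, load_builtin_spec("ct_imaging"),
                   metrics=("c_good",), seed=0)
        assert len(res.folds) == 7
        assert {f.trial_id for f in res.folds} == set(mid_cohort.trial_ids)

    def test_every_patient_predicted_once(self, mid_cohort):
        res = iecv(mid_cohort, load_builtin_spec("ct_imaging"),
                   metrics=("c_good",), seed=0)
        oof = res.oof_predictions
        assert len(oof) == len(mid_cohort)
        assert oof["patient_id"].is_unique

    def test_no_leakage_fingerprint(self, mid_cohort):
        """Perturbing held-out outcomes leaves the fold's coefficients
        unchanged."""
        spec = load_builtin_spec("ct_imaging")
        res = iecv(mid_cohort, spec, metrics=("c_good",), seed=0)
        t0 = mid_cohort.trial_ids[0]
        perturbed = mid_cohort.copy()
        mask = perturbed.data["trial_id"] == t0
        perturbed.data.loc[mask, "mrs90"] = (
            6 - perturbed.data.loc[mask, "mrs90"]
        )
        res2 = iecv(perturbed, spec, metrics=("c_good",), seed=0)
        f0 = next(f for f in res.folds if f.trial_id == t0)
        f0b = next(f for f in res2.folds if f.trial_id == t0)
        assert np.allclose(f0.model.beta, f0b.model.beta, atol=1e-12)

    def test_pooled_within_fold_range(self, mid_cohort):
        res = iecv(mid_cohort, load_builtin_spec("ct_imaging"),
                   metrics=("c_good",), seed=0)
        vals = [f.estimates["c_good"].value for f in res.folds]
        assert min(vals) <= res.pooled["c_good"].value <= max(vals)

    def test_two_trial_minimum(self, mid_cohort):
        one = mid_cohort.trial(mid_cohort.trial_ids[0])
        with pytest.raises(ContractError):
            iecv(one, load_builtin_spec("ct_imaging"))


class TestBootstrapComparison:
    def _oof(self, mid_cohort, spec_name, seed=0):
        return iecv(mid_cohort, load_builtin_spec(spec_name),
                    metrics=("c_good",), seed=seed).oof_predictions

    def test_identical_predictions_give_zero_delta(self, mid_cohort):
        oof = self._oof(mid_cohort, "ct_imaging")
        cmp_ = compare_models_bootstrap(oof, oof.copy(), "c_good", B=100,
                                        seed=1)
        assert cmp_.delta == 0.0
        assert cmp_.ci_low == 0.0 and cmp_.ci_high == 0.0

    def test_seed_determinism(self, mid_cohort):
        a = self._oof(mid_cohort, "ct_imaging")
        b = self._oof(mid_cohort, "ct_extended")
        c1 = compare_models_bootstrap(a, b, "c_good", B=150, seed=3)
        c2 = compare_models_bootstrap(a, b, "c_good", B=150, seed=3)
        assert (c1.delta, c1.ci_low, c1.ci_high) == (c2.delta, c2.ci_low,
                                                     c2.ci_high)

    def test_patient_mismatch_rejected(self, mid_cohort):
        from ctbenefit.validation import AlignmentError

        oof = self._oof(mid_cohort, "ct_imaging")
        other = oof.iloc[:-1]
        with pytest.raises(AlignmentError):
            compare_models_bootstrap(oof, other, "c_good", B=100, seed=0)

    def test_true_probabilities_beat_noise(self, default_config):
        """Predictions corrupted by noise lose concordance; the bootstrap CI
        of the delta excludes zero in most replicates."""
        wins = 0
        reps = 5
        for s in range(reps):
            coh = generate_cohort(
                scale_trials(default_config, 3000, missing_rate=0.0),
                seed=300 + s,
            )
            from ctbenefit.simulate import _linear_predictor
            from scipy.special import expit

            eta = _linear_predictor(default_config, coh.data)
            p_true = expit(default_config.intercepts[2] + eta)
            rng = np.random.default_rng(400 + s)
            noisy = expit(np.log(p_true / (1 - p_true))
                          + rng.normal(0, 2.0, len(p_true)))
            base = pd.DataFrame(
                {"patient_id": coh.data["patient_id"],
                 "trial_id": coh.data["trial_id"],
                 "mrs90": coh.data["mrs90"], "p_good": p_true}
            )
            corrupted = base.assign(p_good=noisy)
            cmp_ = compare_models_bootstrap(base, corrupted, "c_good",
                                            B=200, seed=s)
            if cmp_.ci_low > 0:
                wins += 1
        assert wins >= 0.8 * reps


class TestAddedValue:
    def test_existing_variable_rejected(self, mid_cohort):
        spec = load_builtin_spec("ct_imaging")
        with pytest.raises(ContractError):
            added_value_analysis(mid_cohort, spec,
                                 [Term(kind="linear", variable="aspects")])

    def test_true_omitted_predictor_detected(self, default_config):
        """Adding the generating WML effect (log OR ln(0.80) per 5 mL) to a
        model that omits it improves fit in most replicates at n=5000."""
        spec = load_builtin_spec("ct_imaging")
        base = spec.drop_variable("wml_volume")
        hits = 0
        reps = 8
        for s in range(reps):
            coh = generate_cohort(
                scale_trials(default_config, 5000, missing_rate=0.0),
                seed=500 + s,
            )
            rep = added_value_analysis(
                coh, base,
                [Term(kind="linear", variable="wml_volume", scale=5.0)],
                metrics=("c_good",), seed=s,
            )
            if rep["lrt_p"].iloc[0] < 0.05:
                hits += 1
        assert hits >= 0.8 * reps


class TestFullRun:
    def test_structure_and_determinism(self, default_config):
        cfg = scale_trials(default_config, 700, missing_rate=0.03)
        coh = generate_cohort(cfg, seed=88)
        specs = {
            "ct_imaging": load_builtin_spec("ct_imaging"),
            "ct_extended": load_builtin_spec("ct_extended"),
        }
        kw = dict(m_imputations=1, n_boot=100, seed=9,
                  metrics=("c_ordinal", "c_good", "c_for_benefit"))
        r1 = run_full_analysis(coh, specs, **kw)
        r2 = run_full_analysis(coh, specs, **kw)
        assert set(r1["pooled"]["model"]) == set(specs)
        assert len(r1["pooled"]) == 2 * 3
        pd.testing.assert_frame_equal(r1["performance"], r2["performance"])
        pd.testing.assert_frame_equal(r1["pooled"], r2["pooled"])
        pd.testing.assert_frame_equal(r1["comparisons"], r2["comparisons"])
        assert r1["run_log"]["config_hash"] == r2["run_log"]["config_hash"]
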