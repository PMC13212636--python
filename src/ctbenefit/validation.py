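"""Internal-external cross-validation and meta-analytic model evaluation.

The evaluation design is leave-one-trial-out: the model is re-fitted on
all trials but one, predictions are made for the held-out trial, and the
per-trial performance estimates (one per trial in the pool) are pooled
with DerSimonian-Laird random-effects meta-analysis. Model pairs are
compared by the difference of concordance statistics with a stratified
bootstrap percentile interval. Multiple imputation wraps the whole
procedure; metric values are averaged across completed datasets with
Rubin-style total variance.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benefit import PairSet, c_for_benefit, match_pairs, mean_calibration_benefit
from .cohort import TrialCohort, impute_missing
from .design import ModelSpec, Term
from .metrics import (
    PerformanceEstimate,
    UndefinedMetricError,
    c_binary,
    c_ordinal,
    calibration_slope_intercept,
)
from .ordinal import (
    GOOD_OUTCOME_MAX,
    FittedOrdinalModel,
    build_design_matrix,
    fit_model,
    likelihood_ratio_test,
    predict_benefit,
    predict_good_outcome,
    resolve_spec,
    summarize_effects,
)

__all__ = [
    "PooledEstimate",
    "IECVResult",
    "ModelComparison",
    "iecv",
    "pool_random_effects",
    "compare_models_bootstrap",
    "added_value_analysis",
    "run_full_analysis",
    "DEFAULT_METRICS",
]

DEFAULT_METRICS = (
    "c_ordinal",
    "c_good",
    "calibration_slope",
    "calibration_intercept",
    "c_for_benefit",
    "mean_benefit_calibration",
)


class AlignmentError(ValueError):
    pass


class ContractError(ValueError):
    pass


@dataclass
class PooledEstimate:
    value: float
    ci_low: float
    ci_high: float
    tau2: float
    fold_values: list[float]
    fold_ses: list[float]


@dataclass
class FoldResult:
    trial_id: str
    model: FittedOrdinalModel
    predictions: pd.DataFrame
    estimates: dict[str, PerformanceEstimate | None]
    pairs: PairSet | None = None


@dataclass
class IECVResult:
    folds: list[FoldResult]
    pooled: dict[str, PooledEstimate]
    oof_predictions: pd.DataFrame  # every patient predicted exactly once
    oof_pairs: pd.DataFrame | None = None
    spec_name: str = ""


@dataclass
class ModelComparison:
    metric: str
    delta: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def pool_random_effects(fold_values, fold_ses) -> PooledEstimate:
    """DerSimonian-Laird random-effects pooling with a normal 95% CI."""
    y = np.asarray(fold_values, dtype=float)
    s = np.asarray(fold_ses, dtype=float)
    if y.size != s.size or y.size < 1:
        raise ContractError("need equal-length, non-empty values and SEs")
    if np.any(s <= 0):
        raise ContractError("all fold SEs must be positive")
    if y.size == 1:
        v, se = float(y[0]), float(s[0])
        return PooledEstimate(v, v - 1.96 * se, v + 1.96 * se, 0.0,
                              y.tolist(), s.tolist())
    w = 1.0 / s**2
    ybar = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - ybar) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (y.size - 1)) / denom) if denom > 0 else 0.0
    wstar = 1.0 / (s**2 + tau2)
    pooled = float(np.sum(wstar * y) / np.sum(wstar))
    se_p = float(np.sqrt(1.0 / np.sum(wstar)))
    return PooledEstimate(pooled, pooled - 1.96 * se_p, pooled + 1.96 * se_p,
                          float(tau2), y.tolist(), s.tolist())


def _matching_covariates(spec: ModelSpec) -> list[str]:
    return [v for v in spec.variables() if v != "evt"]


def _fold_metrics(
    held: pd.DataFrame, model: FittedOrdinalModel, metrics, seed: int,
    matching_method: str,
) -> tuple[pd.DataFrame, dict, PairSet | None]:
    dm = build_design_matrix(held, model.spec)
    eta = model.linear_predictor(dm.X)
    p_good = predict_good_outcome(model, dm)
    ben = predict_benefit(model, held)
    preds = pd.DataFrame(
        {
            "patient_id": held["patient_id"].to_numpy(),
            "trial_id": held["trial_id"].to_numpy(),
            "evt": held["evt"].to_numpy(),
            "mrs90": held["mrs90"].to_numpy(),
            "eta": eta,
            "p_good": p_good,
            "p_good_evt": ben["p_good_evt"].to_numpy(),
            "p_good_control": ben["p_good_control"].to_numpy(),
            "benefit": ben["benefit"].to_numpy(),
        }
    )
    good = (preds["mrs90"] <= GOOD_OUTCOME_MAX).astype(int).to_numpy()
    est: dict[str, PerformanceEstimate | None] = {}
    pairs = None
    for m in metrics:
        try:
            if m == "c_ordinal":
                est[m] = c_ordinal(preds["mrs90"].to_numpy(), eta)
            elif m == "c_good":
                est[m] = c_binary(good, p_good)
            elif m in ("calibration_slope", "calibration_intercept"):
                if "calibration_slope" in est or "calibration_intercept" in est:
                    continue
                slope, intercept = calibration_slope_intercept(good, p_good)
                if "calibration_slope" in metrics:
                    est["calibration_slope"] = slope
                if "calibration_intercept" in metrics:
                    est["calibration_intercept"] = intercept
            elif m in ("c_for_benefit", "mean_benefit_calibration"):
                if pairs is None:
                    sub = TrialCohort(held.reset_index(drop=True))
                    pairs = match_pairs(
                        sub, _matching_covariates(model.spec),
                        ben["benefit"].to_numpy(), method=matching_method,
                        seed=seed, within_trial=False,
                    )
                if m == "c_for_benefit":
                    est[m] = c_for_benefit(pairs)
                else:
                    mb = mean_calibration_benefit(pairs)
                    # binomial-difference SE of the observed minus predicted mean
                    se = float(np.std(pairs.observed - pairs.predicted, ddof=1)
                               / np.sqrt(len(pairs)))
                    est[m] = PerformanceEstimate(m, mb, se, len(pairs),
                                                 "matched pairs")
        except (UndefinedMetricError, ValueError) as e:
            warnings.warn(f"metric {m} undefined on fold: {e}")
            est[m] = None
    return preds, est, pairs


def iecv(
    cohort: TrialCohort,
    spec: ModelSpec,
    metrics=DEFAULT_METRICS,
    seed: int = 0,
    matching_method: str = "mahalanobis",
) -> IECVResult:
    """Leave-one-trial-out internal-external cross-validation.

    The spec's variable set is fixed in advance (any elimination happens
    before this call); each fold re-estimates coefficients only. Knots of
    data-driven splines are resolved on each fold's training data. Folds
    on which a metric is undefined are dropped from that metric's pooling
    with a warning.
    """
    if len(cohort.trial_ids) < 2:
        raise ContractError("need at least two trials for leave-one-study-out")
    folds: list[FoldResult] = []
    pair_frames = []
    for t in cohort.trial_ids:
        train = cohort.data[cohort.data["trial_id"] != t].reset_index(drop=True)
        held = cohort.data[cohort.data["trial_id"] == t].reset_index(drop=True)
        model = fit_model(train, spec)
        preds, est, pairs = _fold_metrics(
            held, model, metrics, seed=seed, matching_method=matching_method
        )
        folds.append(FoldResult(trial_id=t, model=model, predictions=preds,
                                estimates=est, pairs=pairs))
        if pairs is not None:
            pf = pairs.to_frame()
            pf["trial_id"] = t
            pair_frames.append(pf)
    pooled = {}
    for m in metrics:
        vals = [f.estimates.get(m) for f in folds]
        vals = [v for v in vals if v is not None and v.se > 0]
        if not vals:
            warnings.warn(f"metric {m} undefined on every fold; not pooled")
            continue
        pooled[m] = pool_random_effects([v.value for v in vals],
                                        [v.se for v in vals])
    oof = pd.concat([f.predictions for f in folds], ignore_index=True)
    oof_pairs = (pd.concat(pair_frames, ignore_index=True)
                 if pair_frames else None)
    return IECVResult(folds=folds, pooled=pooled, oof_predictions=oof,
                      oof_pairs=oof_pairs, spec_name=spec.name)


def _metric_on(frame: pd.DataFrame, metric: str, value_col: str) -> float:
    if metric == "c_good":
        good = (frame["mrs90"] <= GOOD_OUTCOME_MAX).astype(int).to_numpy()
        return c_binary(good, frame[value_col].to_numpy()).value
    if metric == "c_for_benefit":
        from .metrics import concordance_with_jackknife

        c, _, _ = concordance_with_jackknife(
            frame["observed"].to_numpy(), frame[value_col].to_numpy()
        )
        return c
    raise ContractError(f"unsupported comparison metric {metric!r}")


def compare_models_bootstrap(
    preds_A: pd.DataFrame,
    preds_B: pd.DataFrame,
    metric: str = "c_good",
    B: int = 500,
    seed: int = 0,
) -> ModelComparison:
    """Delta concordance (A minus B) with a stratified bootstrap percentile CI.

    For ``c_good`` the inputs are out-of-fold prediction tables covering
    identical patients; for ``c_for_benefit`` they are matched-pair tables
    (columns observed/predicted) covering identical pairs. Resampling is
    with replacement, stratified by trial, with both metrics recomputed on
    the same resample.
    """
    if B < 100:
        raise ContractError("B must be >= 100")
    if metric == "c_good":
        key, value_col = "patient_id", "p_good"
    else:
        key, value_col = None, "predicted"
    A = preds_A.reset_index(drop=True)
    Bf = preds_B.reset_index(drop=True)
    if len(A) != len(Bf):
        raise AlignmentError("prediction sets differ in size")
    if key is not None:
        if set(A[key]) != set(Bf[key]):
            raise AlignmentError("prediction sets cover different patients")
        Bf = Bf.set_index(key).loc[A[key]].reset_index()
    delta = _metric_on(A, metric, value_col) - _metric_on(Bf, metric, value_col)

    rng = np.random.default_rng(seed)
    strata = [np.flatnonzero(A["trial_id"].to_numpy() == t)
              for t in pd.unique(A["trial_id"])]
    deltas = np.empty(B)
    for b in range(B):
        idx = np.concatenate(
            [s[rng.integers(0, s.size, s.size)] for s in strata]
        )
        Ab, Bb = A.iloc[idx], Bf.iloc[idx]
        try:
            deltas[b] = (_metric_on(Ab, metric, value_col)
                         - _metric_on(Bb, metric, value_col))
        except UndefinedMetricError:
            deltas[b] = np.nan
    deltas = deltas[~np.isnan(deltas)]
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return ModelComparison(metric=metric, delta=float(delta),
                           ci_low=float(min(lo, delta)),
                           ci_high=float(max(hi, delta)),
                           n_boot=B, seed=seed)


def added_value_analysis(
    cohort: TrialCohort,
    base_spec: ModelSpec,
    add_terms: list[Term],
    metrics=("c_good", "c_for_benefit"),
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sequentially add each candidate term to the base model.

    Per candidate: full-data likelihood-ratio test against the base; when
    the fit improves (p < alpha), run cross-validation on the extended
    spec and report the change in pooled metrics versus the base.
    """
    data = cohort.data
    base_vars = set(base_spec.variables())
    for t in add_terms:
        if t.variable in base_vars:
            raise ContractError(f"variable {t.variable!r} already in base spec")
    rbase = resolve_spec(base_spec, data)
    base_fit = fit_model(data, rbase)
    base_iecv_res = None
    rows = []
    for t in add_terms:
        ext = rbase.with_terms([t], name=f"{base_spec.name}+{t.variable}")
        ext_fit = fit_model(data, ext)
        stat, df, p = likelihood_ratio_test(ext_fit, base_fit)
        row = {"variable": t.variable, "lrt_stat": stat, "lrt_df": df, "lrt_p": p}
        if p < alpha:
            if base_iecv_res is None:
                base_iecv_res = iecv(cohort, rbase, metrics=metrics, seed=seed)
            ext_res = iecv(cohort, ext, metrics=metrics, seed=seed)
            for m in metrics:
                if m in ext_res.pooled and m in base_iecv_res.pooled:
                    row[f"delta_{m}"] = (ext_res.pooled[m].value
                                         - base_iecv_res.pooled[m].value)
        rows.append(row)
    return pd.DataFrame(rows)


def _rubin_combine(values: list[float], ses: list[float]) -> tuple[float, float]:
    """Pool an estimate across completed datasets: mean value, total SE
    (within-imputation variance plus (1+1/m) between-imputation variance)."""
    v = np.asarray(values, float)
    s = np.asarray(ses, float)
    m = v.size
    if m == 1:
        return float(v[0]), float(s[0])
    between = np.var(v, ddof=1)
    total = np.mean(s**2) + (1 + 1 / m) * between
    return float(v.mean()), float(np.sqrt(total))


def run_full_analysis(
    cohort: TrialCohort,
    specs: dict[str, ModelSpec],
    m_imputations: int = 5,
    n_boot: int = 500,
    seed: int = 0,
    metrics=DEFAULT_METRICS,
    matching_method: str = "mahalanobis",
) -> dict:
    """Full evaluation: imputation -> per-imputation IECV per model ->
    Rubin combination per fold -> random-effects pooling -> pairwise
    bootstrap comparisons -> odds-ratio and performance tables.

    Returns a dict of tidy DataFrames plus a JSON-able run log.
    """
    completed = impute_missing(cohort, m=m_imputations, seed=seed)
    results: dict[str, list[IECVResult]] = {}
    or_tables = {}
    for name, spec in specs.items():
        per_imp = [
            iecv(c, spec, metrics=metrics, seed=seed,
                 matching_method=matching_method)
            for c in completed
        ]
        results[name] = per_imp
        fits = [fit_model(c.data, spec) for c in completed]
        # Rubin-combined coefficient table on the full development data
        base = summarize_effects(fits[0])
        if m_imputations > 1:
            betas = np.mean([f.beta for f in fits], axis=0)
            within = np.mean([np.diag(f.cov)[f.alpha.size:] for f in fits], axis=0)
            between = np.var([f.beta for f in fits], axis=0, ddof=1)
            tot_se = np.sqrt(within + (1 + 1 / m_imputations) * between)
            # rebuild simple per-column rows (splines summarized per column here)
            base = pd.DataFrame({
                "term": fits[0].term_of_column,
                "label": fits[0].labels,
                "or": np.exp(betas),
                "ci_low": np.exp(betas - 1.96 * tot_se),
                "ci_high": np.exp(betas + 1.96 * tot_se),
            })
        or_tables[name] = base

    # per-fold Rubin combination, then pooling
    perf_rows = []
    pooled_tables: dict[str, dict[str, PooledEstimate]] = {}
    trial_ids = cohort.trial_ids
    for name, per_imp in results.items():
        pooled_tables[name] = {}
        for metric in metrics:
            fold_vals, fold_ses = [], []
            for fi, t in enumerate(trial_ids):
                ests = [r.folds[fi].estimates.get(metric) for r in per_imp]
                ests = [e for e in ests if e is not None]
                if not ests:
                    continue
                v, s = _rubin_combine([e.value for e in ests],
                                      [e.se for e in ests])
                fold_vals.append(v)
                fold_ses.append(s)
                perf_rows.append({"model": name, "metric": metric,
                                  "fold": t, "value": v, "se": s})
            if fold_vals:
                pooled_tables[name][metric] = pool_random_effects(fold_vals,
                                                                  fold_ses)
    performance = pd.DataFrame(perf_rows)
    pooled_df = pd.DataFrame(
        [
            {"model": name, "metric": m, "value": pe.value,
             "ci_low": pe.ci_low, "ci_high": pe.ci_high, "tau2": pe.tau2}
            for name, table in pooled_tables.items()
            for m, pe in table.items()
        ]
    )

    # pairwise comparisons on imputation-averaged out-of-fold predictions
    def avg_oof(per_imp):
        oof = per_imp[0].oof_predictions.copy()
        for col in ("eta", "p_good", "benefit"):
            oof[col] = np.mean([r.oof_predictions[col].to_numpy()
                                for r in per_imp], axis=0)
        return oof

    comparisons = []
    names = list(specs)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            cmp_good = compare_models_bootstrap(
                avg_oof(results[a]), avg_oof(results[b]), "c_good",
                B=n_boot, seed=seed,
            )
            comparisons.append({"model_a": a, "model_b": b,
                                "metric": "c_good", "delta": cmp_good.delta,
                                "ci_low": cmp_good.ci_low,
                                "ci_high": cmp_good.ci_high})
            pa = results[a][0].oof_pairs
            pb = results[b][0].oof_pairs
            if pa is not None and pb is not None and len(pa) == len(pb):
                cmp_ben = compare_models_bootstrap(pa, pb, "c_for_benefit",
                                                   B=n_boot, seed=seed)
                comparisons.append({"model_a": a, "model_b": b,
                                    "metric": "c_for_benefit",
                                    "delta": cmp_ben.delta,
                                    "ci_low": cmp_ben.ci_low,
                                    "ci_high": cmp_ben.ci_high})
    comparisons = pd.DataFrame(comparisons)

    run_cfg = {"seed": seed, "m_imputations": m_imputations, "n_boot": n_boot,
               "metrics": list(metrics), "models": names,
               "matching_method": matching_method}
    cfg_hash = hashlib.sha256(
        json.dumps(run_cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    return {
        "performance": performance,
        "pooled": pooled_df,
        "comparisons": comparisons,
        "or_tables": or_tables,
        "pooled_objects": pooled_tables,
        "iecv_results": results,
        "run_log": {**run_cfg, "config_hash": cfg_hash},
    }
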