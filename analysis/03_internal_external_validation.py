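"""Leave-one-trial-out validation of the three models.

For each model: seven held-out-trial estimates of ordinal C, C for good
outcome (mRS 0-2), calibration slope/intercept, and the matched-pair
benefit metrics, pooled by DerSimonian-Laird random-effects
meta-analysis. Writes the per-fold table (forest-plot data) and the
pooled performance table.
"""

from pathlib import Path

import pandas as pd

from ctbenefit import iecv, load_builtin_spec, impute_missing, read_cohort

SEED = 20260929
OUT = Path("results")


def main():
    cohort = read_cohort(OUT / "cohort.csv")
    completed = impute_missing(cohort, m=5, seed=SEED)[0]

    perf_rows, pooled_rows = [], []
    for name in ("ct_imaging", "ct_extended", "mr_predicts_ref"):
        res = iecv(completed, load_builtin_spec(name), seed=SEED)
        for f in res.folds:
            for m, est in f.estimates.items():
                if est is not None:
                    perf_rows.append({"model": name, "metric": m,
                                      "fold": f.trial_id,
                                      "value": est.value, "se": est.se})
        for m, pe in res.pooled.items():
            pooled_rows.append({"model": name, "metric": m,
                                "value": pe.value, "ci_low": pe.ci_low,
                                "ci_high": pe.ci_high, "tau2": pe.tau2})
        p = res.pooled
        print(f"{name}:")
        print(f"  C (ordinal)      {p['c_ordinal'].value:.3f} "
              f"({p['c_ordinal'].ci_low:.3f}-{p['c_ordinal'].ci_high:.3f})")
        print(f"  C (mRS 0-2)      {p['c_good'].value:.3f} "
              f"({p['c_good'].ci_low:.3f}-{p['c_good'].ci_high:.3f})")
        print(f"  slope            {p['calibration_slope'].value:.3f}")
        print(f"  intercept        {p['calibration_intercept'].value:+.3f}")
        print(f"  C-for-benefit    {p['c_for_benefit'].value:.3f}")
        print(f"  mean benefit cal {p['mean_benefit_calibration'].value:+.3f}")

    pd.DataFrame(perf_rows).to_csv(OUT / "forest.csv", index=False)
    pd.DataFrame(pooled_rows).to_csv(OUT / "pooled_performance.csv",
                                     index=False)
    print(f"wrote {OUT / 'forest.csv'} and {OUT / 'pooled_performance.csv'}")


if __name__ == "__main__":
    main()
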