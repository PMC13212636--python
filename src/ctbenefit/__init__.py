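"""Ordinal prediction of post-stroke outcome and thrombectomy benefit.

The package fits proportional-odds models of the 90-day modified Rankin
Scale from baseline CT-derived and clinical covariates, predicts
individual treatment benefit (difference in probability of mRS 0-2 with
vs without endovascular thrombectomy), and validates both with
leave-one-trial-out internal-external cross-validation, matched-pair
C-for-benefit, and random-effects pooling. A synthetic multi-trial
cohort generator supplies data with the covariate structure and outcome
process the models assume.
"""

from importlib import resources

from .benefit import (
    PairSet,
    benefit_calibration_curve,
    c_for_benefit,
    match_pairs,
    mean_calibration_benefit,
)
from .cohort import (
    TrialCohort,
    impute_missing,
    read_cohort,
    validate_cohort,
    write_cohort,
)
from .config import RunConfig, parse_config
from .design import (
    DesignMatrix,
    ModelSpec,
    SplineSpec,
    Term,
    build_design_matrix,
    default_knots,
    rcs_basis,
    resolve_spec,
)
from .metrics import (
    PerformanceEstimate,
    c_binary,
    c_ordinal,
    calibration_curve,
    calibration_slope_intercept,
)
from .ordinal import (
    FittedOrdinalModel,
    backward_eliminate,
    fit_model,
    fit_proportional_odds,
    likelihood_ratio_test,
    predict_benefit,
    predict_distribution,
    predict_good_outcome,
    summarize_effects,
)
from .simulate import (
    GeneratorConfig,
    TrialSpec,
    calibrate_intercepts,
    default_hermes_config,
    generate_cohort,
    scale_trials,
    with_intercepts,
)
from .validation import (
    IECVResult,
    ModelComparison,
    PooledEstimate,
    added_value_analysis,
    compare_models_bootstrap,
    iecv,
    pool_random_effects,
    run_full_analysis,
)

__version__ = "0.1.0"


def load_builtin_spec(name: str) -> ModelSpec:
    """Load one of the shipped model specifications:
    'ct_imaging', 'ct_extended', or 'mr_predicts_ref'."""
    ref = resources.files("ctbenefit") / "specs" / f"{name}.json"
    import json

    return ModelSpec.from_dict(json.loads(ref.read_text()))
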