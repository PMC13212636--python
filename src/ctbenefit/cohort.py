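"""Patient-level cohort container, validated CSV I/O, and multiple imputation.

A cohort is one row per randomized patient: trial label, treatment arm
(EVT vs standard care), 90-day modified Rankin Scale (mRS, 0-6), and the
baseline clinical and CT-derived covariates used by the prediction models.
trial_id, evt and mrs90 are always required; any covariate may be missing
and is imputed with chained equations before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CATEGORY_LEVELS

__all__ = [
    "TrialCohort",
    "COLUMN_ORDER",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "impute_missing",
]

# Fixed column dictionary; categorical codes are stored as strings.
COLUMN_ORDER = [
    "patient_id",
    "trial_id",
    "evt",
    "mrs90",
    "age",
    "nihss",
    "sbp",
    "glucose",
    "prestroke_mrs",
    "diabetes",
    "iv_alteplase",
    "onset_to_groin",
    "aspects",
    "occlusion",
    "collateral",
    "wml_volume",
    "bpf",
    "old_infarct_volume",
    "icac",
]

REQUIRED = ("patient_id", "trial_id", "evt", "mrs90")
CONTINUOUS = ("age", "sbp", "glucose", "onset_to_groin", "wml_volume", "bpf",
              "old_infarct_volume")
DISCRETE = ("nihss", "prestroke_mrs", "aspects", "collateral")
BINARY = ("diabetes", "iv_alteplase")
CATEGORICAL = ("occlusion", "icac")
COVARIATES = CONTINUOUS + DISCRETE + BINARY + CATEGORICAL

# (low, high) inclusive bounds for bounded numeric fields; None = unbounded.
_BOUNDS = {
    "mrs90": (0, 6),
    "evt": (0, 1),
    "nihss": (0, 42),
    "prestroke_mrs": (0, 5),
    "aspects": (0, 10),
    "collateral": (0, 3),
    "diabetes": (0, 1),
    "iv_alteplase": (0, 1),
    "wml_volume": (0, None),
    "old_infarct_volume": (0, None),
    "bpf": (0, 100),
}


class SchemaError(ValueError):
    pass


class RecordError(ValueError):
    pass


class IntegrityError(ValueError):
    pass


class UnimputableError(ValueError):
    pass


@dataclass
class TrialCohort:
    """Ordered patient table plus the ordered list of distinct trial labels."""

    data: pd.DataFrame
    trial_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.trial_ids:
            self.trial_ids = list(pd.unique(self.data["trial_id"].astype(str)))

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "TrialCohort":
        return TrialCohort(self.data.loc[mask].reset_index(drop=True))

    def trial(self, trial_id: str) -> "TrialCohort":
        return self.subset(self.data["trial_id"] == trial_id)

    def copy(self) -> "TrialCohort":
        return TrialCohort(self.data.copy(), list(self.trial_ids))


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for c in ("patient_id", "trial_id"):
        df[c] = df[c].astype(str)
    for c in CATEGORICAL:
        if c in df:
            df[c] = df[c].where(df[c].notna(), other=pd.NA)
            df[c] = df[c].astype("string")
    numeric = [c for c in COLUMN_ORDER if c not in ("patient_id", "trial_id") + CATEGORICAL]
    for c in numeric:
        if c in df:
            df[c] = pd.to_numeric(df[c], errors="raise")
    return df


def read_cohort(path, schema_strict: bool = True) -> TrialCohort:
    """Read a patient CSV into a validated cohort.

    Missing covariates are empty cells (NaN/NA after parsing). In strict
    mode any column outside the documented dictionary is a schema error;
    otherwise extras are dropped.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "trial_id": str})
    unknown = [c for c in df.columns if c not in COLUMN_ORDER]
    if unknown and schema_strict:
        raise SchemaError(f"unknown columns: {unknown}")
    missing_cols = [c for c in COLUMN_ORDER if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing columns: {missing_cols}")
    df = _coerce(df[COLUMN_ORDER])
    for c in REQUIRED:
        bad = df[c].isna()
        if bad.any():
            raise RecordError(f"row {int(np.flatnonzero(bad)[0])}: {c} is required")
    bad = ~df["mrs90"].isin(range(7))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise RecordError(f"row {row}: mrs90={df['mrs90'].iloc[row]} outside 0-6")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise IntegrityError(f"duplicate patient_id {dup!r}")
    cohort = TrialCohort(df.reset_index(drop=True))
    if schema_strict:
        violations = validate_cohort(cohort)
        field_violations = [v for v in violations if v[0] is not None]
        if field_violations:
            pid, fieldname, rule = field_violations[0]
            raise RecordError(f"patient {pid}: {fieldname} {rule}")
    return cohort


def write_cohort(cohort: TrialCohort, path) -> str:
    """Write the cohort as CSV in the fixed column order; absent values as
    empty fields."""
    df = cohort.data[COLUMN_ORDER]
    df.to_csv(path, index=False, na_rep="")
    return str(path)


def validate_cohort(cohort: TrialCohort) -> list[tuple]:
    """Report invariant violations as (patient_id, field, rule) tuples.

    Cohort-level violations (e.g. a trial with no control arm) carry
    patient_id None. Returns [] iff the cohort is fully valid.
    """
    df = cohort.data
    out: list[tuple] = []
    int_fields = ("mrs90", "evt", "nihss", "prestroke_mrs", "aspects",
                  "collateral", "diabetes", "iv_alteplase")
    for c, (lo, hi) in _BOUNDS.items():
        vals = df[c]
        mask = pd.Series(False, index=df.index)
        if lo is not None:
            mask |= vals < lo
        if hi is not None:
            mask |= vals > hi
        if c == "bpf":
            mask |= vals <= 0  # bpf must be strictly positive
        if c in int_fields:
            mask |= vals.notna() & (vals != vals.round())
        for pid in df.loc[mask.fillna(False), "patient_id"]:
            out.append((pid, c, f"outside [{lo}, {hi}] or non-integer"))
    for c in CATEGORICAL:
        levels = CATEGORY_LEVELS[c]
        bad = df[c].notna() & ~df[c].isin(levels)
        for pid in df.loc[bad, "patient_id"]:
            out.append((pid, c, f"not in {levels}"))
    dup = df["patient_id"].duplicated()
    for pid in df.loc[dup, "patient_id"]:
        out.append((pid, "patient_id", "duplicate"))
    for t in cohort.trial_ids:
        arm = df.loc[df["trial_id"] == t, "evt"]
        if (arm == 1).sum() == 0:
            out.append((None, "trial:" + t, "no treated patients"))
        if (arm == 0).sum() == 0:
            out.append((None, "trial:" + t, "no control patients"))
    return out


# ---------------------------------------------------------------------------
# Multiple imputation by chained equations
# ---------------------------------------------------------------------------

def _design_for_imputation(df: pd.DataFrame, exclude: str) -> np.ndarray:
    """Numeric predictor matrix for one chained-equation step: all other
    covariates plus treatment arm and the outcome, categoricals dummy-coded."""
    cols = []
    for c in ("evt", "mrs90") + CONTINUOUS + DISCRETE + BINARY:
        if c != exclude:
            cols.append(np.asarray(df[c], dtype=float))
    for c in CATEGORICAL:
        if c == exclude:
            continue
        vals = df[c].astype(str).to_numpy()
        for lev in CATEGORY_LEVELS[c][1:]:
            cols.append((vals == lev).astype(float))
    return np.column_stack(cols)


def _draw_continuous(X, y, miss, rng):
    """Bayesian-flavoured linear-regression draw: coefficients perturbed by
    their estimated covariance, residual noise added."""
    Xo, yo = X[~miss], y[~miss]
    A = np.column_stack([np.ones(len(Xo)), Xo])
    coef, res, *_ = np.linalg.lstsq(A, yo, rcond=None)
    fitted = A @ coef
    dof = max(len(yo) - A.shape[1], 1)
    sigma = np.sqrt(np.sum((yo - fitted) ** 2) / dof)
    XtX = A.T @ A + 1e-8 * np.eye(A.shape[1])
    cov = sigma**2 * np.linalg.inv(XtX)
    coef_draw = rng.multivariate_normal(coef, cov)
    Am = np.column_stack([np.ones(miss.sum()), X[miss]])
    return Am @ coef_draw + rng.normal(0, sigma, miss.sum())


def _draw_categorical(X, y_codes, n_levels, miss, rng):
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    Xo, yo = Xz[~miss], y_codes[~miss]
    if np.unique(yo).size < 2:
        return np.full(miss.sum(), yo[0])
    clf = LogisticRegression(max_iter=300, C=1.0)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xo, yo)
    probs = clf.predict_proba(Xz[miss])
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(probs))[:, None]
    picks = (u > cum).sum(axis=1)
    return clf.classes_[picks]


def impute_missing(cohort: TrialCohort, m: int = 5, seed: int = 0,
                   n_cycles: int = 10) -> list[TrialCohort]:
    """Multiple imputation of missing covariates by chained equations.

    Returns ``m`` completed cohorts. Continuous and count covariates are
    imputed with linear-regression draws (counts rounded and clipped to
    their ranges), binary and categorical covariates with multinomial
    logistic draws. The outcome and treatment arm are always included as
    predictors. Observed values are never altered; results are
    deterministic under a fixed seed.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    df0 = cohort.data
    with_missing = [c for c in COVARIATES if df0[c].isna().any()]
    for c in with_missing:
        if df0[c].notna().sum() == 0:
            raise UnimputableError(f"covariate {c!r} is entirely missing")
    if not with_missing:
        return [cohort.copy() for _ in range(m)]

    rng = np.random.default_rng(seed)
    out = []
    int_like = set(DISCRETE + BINARY)
    for _ in range(m):
        df = df0.copy()
        # initial fill: random draws from the observed marginal
        for c in with_missing:
            miss = df[c].isna().to_numpy()
            obs = df.loc[~miss, c].to_numpy()
            df.loc[miss, c] = rng.choice(obs, miss.sum(), replace=True)
        for _cycle in range(n_cycles):
            for c in with_missing:
                miss = df0[c].isna().to_numpy()
                X = _design_for_imputation(df, exclude=c)
                if c in CATEGORICAL:
                    levels = list(CATEGORY_LEVELS[c])
                    codes = df[c].map({lv: i for i, lv in enumerate(levels)}).to_numpy()
                    drawn = _draw_categorical(X, codes.astype(int), len(levels), miss, rng)
                    df.loc[miss, c] = [levels[int(k)] for k in drawn]
                else:
                    y = np.asarray(df[c], dtype=float)
                    drawn = _draw_continuous(X, y, miss, rng)
                    if c in int_like:
                        lo, hi = _BOUNDS.get(c, (None, None))
                        drawn = np.round(drawn)
                        if lo is not None:
                            drawn = np.clip(drawn, lo, hi)
                    elif c in ("wml_volume", "old_infarct_volume"):
                        drawn = np.clip(drawn, 0.0, None)
                    elif c == "bpf":
                        drawn = np.clip(drawn, 1e-6, 100.0)
                    df.loc[miss, c] = drawn
        out.append(TrialCohort(df, list(cohort.trial_ids)))
    return out
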