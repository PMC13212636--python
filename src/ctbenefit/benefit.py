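"""Matched-pair treatment-benefit validation.

Individual treatment effects are unobservable, so observed benefit is
defined on 1:1 treated-control pairs matched on baseline covariates:
the good-outcome indicator of the treated member minus that of the
control member (-1, 0, or 1). Predicted pair benefit is the mean of the
two members' model-predicted benefits. The C-for-benefit is then the
concordance, across pairs of pairs with unequal observed benefit, between
observed and predicted benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import TrialCohort
from .design import CATEGORY_LEVELS
from .metrics import PerformanceEstimate, concordance_with_jackknife
from .ordinal import GOOD_OUTCOME_MAX

__all__ = [
    "MatchedPair",
    "PairSet",
    "match_pairs",
    "c_for_benefit",
    "mean_calibration_benefit",
    "benefit_calibration_curve",
]


class MatchingError(ValueError):
    pass


@dataclass
class MatchedPair:
    treated_id: str
    control_id: str
    distance: float
    observed: int  # good-outcome indicator treated minus control: -1, 0, 1
    predicted: float  # mean of the two members' predicted benefits


@dataclass
class PairSet:
    pairs: list[MatchedPair]
    method: str
    covariates: list[str] = field(default_factory=list)

    def __len__(self):
        return len(self.pairs)

    @property
    def observed(self) -> np.ndarray:
        return np.array([p.observed for p in self.pairs], dtype=float)

    @property
    def predicted(self) -> np.ndarray:
        return np.array([p.predicted for p in self.pairs], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"treated_id": p.treated_id, "control_id": p.control_id,
                 "distance": p.distance, "observed": p.observed,
                 "predicted": p.predicted}
                for p in self.pairs
            ]
        )


def _numeric_matrix(df: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for c in covariates:
        if c in CATEGORY_LEVELS:
            vals = df[c].astype(str).to_numpy()
            for lev in CATEGORY_LEVELS[c][1:]:
                cols.append((vals == lev).astype(float))
        else:
            cols.append(np.asarray(df[c], dtype=float))
    return np.column_stack(cols)


def _greedy_match(dist: np.ndarray, rng: np.random.Generator):
    """Accept treated-control pairs in ascending distance order, each
    patient used at most once; ties broken by a seeded shuffle."""
    nt, nc = dist.shape
    flat = dist.ravel()
    perm = rng.permutation(flat.size)  # random tie-break
    order = perm[np.argsort(flat[perm], kind="stable")]
    used_t = np.zeros(nt, bool)
    used_c = np.zeros(nc, bool)
    out = []
    target = min(nt, nc)
    for k in order:
        i, j = divmod(k, nc)
        if used_t[i] or used_c[j]:
            continue
        used_t[i] = used_c[j] = True
        out.append((i, j, float(dist[i, j])))
        if len(out) == target:
            break
    return out


def match_pairs(
    cohort: TrialCohort,
    covariates: list[str],
    predicted_benefit: pd.Series | np.ndarray,
    method: str = "mahalanobis",
    seed: int = 0,
    within_trial: bool = True,
    ridge: float = 1e-6,
) -> PairSet:
    """Greedy 1:1 nearest-neighbour matching of treated to control patients.

    method 'mahalanobis': distance over the standardized covariates
    (categoricals dummy-coded), covariance ridge-regularized by ``ridge``
    on the diagonal. method 'predicted_benefit': absolute difference of
    the model-predicted benefits. Matching is within trial by default
    (randomization holds within trial); the number of pairs equals
    min(n_treated, n_control) per matching stratum.
    """
    df = cohort.data.reset_index(drop=True)
    pb = np.asarray(predicted_benefit, dtype=float)
    if pb.size != len(df):
        raise MatchingError("predicted_benefit length mismatch")
    good = (df["mrs90"].to_numpy() <= GOOD_OUTCOME_MAX).astype(int)
    rng = np.random.default_rng(seed)

    strata = (
        [df.index[df["trial_id"] == t].to_numpy() for t in cohort.trial_ids]
        if within_trial
        else [df.index.to_numpy()]
    )
    pairs: list[MatchedPair] = []
    for ix in strata:
        sub = df.loc[ix]
        t_ix = ix[sub["evt"].to_numpy() == 1]
        c_ix = ix[sub["evt"].to_numpy() == 0]
        if t_ix.size == 0 or c_ix.size == 0:
            raise MatchingError("stratum lacks a treated or control patient")
        if method == "mahalanobis":
            Z = _numeric_matrix(df.loc[ix], covariates)
            if np.isnan(Z).any():
                raise MatchingError("matching covariates contain missing values")
            Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
            cov = np.cov(Z, rowvar=False) + ridge * np.eye(Z.shape[1])
            try:
                VI = np.linalg.inv(cov)
            except np.linalg.LinAlgError as e:
                raise MatchingError(
                    "singular covariance; increase ridge regularization"
                ) from e
            pos = {g: k for k, g in enumerate(ix)}
            Zt = Z[[pos[i] for i in t_ix]]
            Zc = Z[[pos[i] for i in c_ix]]
            diff = Zt[:, None, :] - Zc[None, :, :]
            dist = np.sqrt(np.clip(np.einsum("ijk,kl,ijl->ij", diff, VI, diff), 0, None))
        elif method == "predicted_benefit":
            dist = np.abs(pb[t_ix][:, None] - pb[c_ix][None, :])
        else:
            raise MatchingError(f"unknown matching method {method!r}")
        for i, j, d in _greedy_match(dist, rng):
            ti, ci = t_ix[i], c_ix[j]
            pairs.append(
                MatchedPair(
                    treated_id=str(df.loc[ti, "patient_id"]),
                    control_id=str(df.loc[ci, "patient_id"]),
                    distance=d,
                    observed=int(good[ti] - good[ci]),
                    predicted=float((pb[ti] + pb[ci]) / 2),
                )
            )
    return PairSet(pairs=pairs, method=method, covariates=list(covariates))


def c_for_benefit(pairs: PairSet) -> PerformanceEstimate:
    """Concordance between observed and predicted benefit across matched pairs.

    Over all pair-of-pair comparisons with unequal observed benefit, the
    fraction in which the pair with greater observed benefit has the
    strictly greater predicted benefit (predicted ties count 0.5);
    jackknife SE over pairs.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    c, se, ncomp = concordance_with_jackknife(pairs.observed, pairs.predicted)
    return PerformanceEstimate("c_for_benefit", c, se, ncomp, "jackknife over pairs")


def mean_calibration_benefit(pairs: PairSet) -> float:
    """Mean observed minus mean predicted pair benefit.

    Positive values mean the model under-predicts benefit on average.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair set")
    return float(pairs.observed.mean() - pairs.predicted.mean())


def benefit_calibration_curve(pairs: PairSet, n_bins: int = 5) -> pd.DataFrame:
    """Quantile-binned predicted vs observed pair benefit (counts sum to m)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    m = len(pairs)
    if m < n_bins:
        raise ValueError("fewer pairs than bins")
    pred, obs = pairs.predicted, pairs.observed
    edges = np.unique(np.quantile(pred, np.linspace(0, 1, n_bins + 1)))
    idx = (
        np.clip(np.searchsorted(edges, pred, side="right") - 1, 0, edges.size - 2)
        if edges.size >= 2
        else np.zeros(m, dtype=int)
    )
    rows = []
    for b in range(max(edges.size - 1, 1)):
        msk = idx == b
        if not msk.any():
            continue
        rows.append(
            {"bin": b, "pred_mean": float(pred[msk].mean()),
             "obs_mean": float(obs[msk].mean()), "n": int(msk.sum())}
        )
    return pd.DataFrame(rows).sort_values("pred_mean").reset_index(drop=True)
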