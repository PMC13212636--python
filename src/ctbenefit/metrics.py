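"""Discrimination and calibration of outcome predictions.

Concordance statistics are computed by a grouped rank algorithm
(O(L * n log n) for L distinct outcome levels) with leave-one-out
jackknife standard errors obtained from per-patient pair sums, so no
resampling is needed. Calibration slope and intercept follow the
logistic-recalibration convention: slope from a logistic regression of
the outcome on the prediction's logit, intercept from the same
regression with the logit held as a fixed offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit

__all__ = [
    "PerformanceEstimate",
    "c_ordinal",
    "c_binary",
    "calibration_slope_intercept",
    "calibration_curve",
]

CLIP = 1e-6


class UndefinedMetricError(ValueError):
    pass


@dataclass
class PerformanceEstimate:
    metric: str
    value: float
    se: float
    n_effective: int
    note: str = ""


def concordance_with_jackknife(goodness, score):
    """Concordance of ``score`` for the ordering ``goodness`` (higher = better).

    Over all pairs with unequal goodness, a pair scores 1 when the member
    with greater goodness has the strictly higher score, 0.5 on a score
    tie. Returns (C, jackknife SE, number of informative pairs).
    """
    goodness = np.asarray(goodness, dtype=float)
    score = np.asarray(score, dtype=float)
    n = goodness.size
    levels = np.unique(goodness)
    if levels.size < 2:
        raise UndefinedMetricError("all observed values equal; concordance undefined")

    groups = {lv: np.flatnonzero(goodness == lv) for lv in levels}
    sorted_scores = {lv: np.sort(score[ix]) for lv, ix in groups.items()}
    s_i = np.zeros(n)  # sum of pair scores involving i
    d_i = np.zeros(n)  # informative pairs involving i
    for a_pos in range(levels.size):
        for b_pos in range(a_pos + 1, levels.size):
            la, lb = levels[a_pos], levels[b_pos]  # lb is the better level
            A, B = groups[la], groups[lb]
            As, Bs = sorted_scores[la], sorted_scores[lb]
            # contributions to members of B (the better group)
            lo = np.searchsorted(As, score[B], side="left")
            hi = np.searchsorted(As, score[B], side="right")
            s_i[B] += lo + 0.5 * (hi - lo)
            d_i[B] += A.size
            # same pairs, seen from members of A
            lo = np.searchsorted(Bs, score[A], side="left")
            hi = np.searchsorted(Bs, score[A], side="right")
            s_i[A] += (B.size - hi) + 0.5 * (hi - lo)
            d_i[A] += B.size

    D = d_i.sum() / 2
    S = s_i.sum() / 2
    c = S / D
    informative = d_i > 0
    loo = np.where(
        (d_i < D) & informative, (S - s_i) / np.where(d_i < D, D - d_i, 1.0), c
    )
    loo = np.where(informative, loo, c)
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    return float(c), se, int(D)


def c_ordinal(observed, score) -> PerformanceEstimate:
    """Harrell's C for the full ordinal outcome.

    ``score`` is oriented so that a higher value predicts a better outcome
    (lower mRS); the model's linear predictor has this orientation.
    """
    observed = np.asarray(observed)
    c, se, npairs = concordance_with_jackknife(-observed.astype(float), score)
    return PerformanceEstimate("c_ordinal", c, se, npairs, "jackknife SE")


def c_binary(observed_good, p_good) -> PerformanceEstimate:
    """Concordance (AUC) of predicted good-outcome probability."""
    observed_good = np.asarray(observed_good, dtype=float)
    if np.unique(observed_good).size < 2:
        raise UndefinedMetricError("single-class outcome; C undefined")
    c, se, npairs = concordance_with_jackknife(observed_good, p_good)
    return PerformanceEstimate("c_good", c, se, npairs, "jackknife SE")


def _clip(p):
    return np.clip(np.asarray(p, dtype=float), CLIP, 1 - CLIP)


def calibration_slope_intercept(observed_good, p_good):
    """(slope PerformanceEstimate, intercept PerformanceEstimate).

    Slope: coefficient of logit(p) in a logistic regression of the
    observed indicator. Intercept: estimated with logit(p) as an offset
    (slope fixed at 1), the calibration-in-the-large convention.
    """
    import statsmodels.api as sm

    y = np.asarray(observed_good, dtype=float)
    if np.unique(y).size < 2:
        raise UndefinedMetricError("single-class outcome; calibration undefined")
    lp = logit(_clip(p_good))
    if np.std(lp) < 1e-12:
        raise UndefinedMetricError("constant predictions; calibration slope undefined")
    n = y.size
    Xs = np.column_stack([np.ones(n), lp])
    fit_s = sm.GLM(y, Xs, family=sm.families.Binomial()).fit()
    slope = PerformanceEstimate(
        "calibration_slope", float(fit_s.params[1]), float(fit_s.bse[1]), n,
        "logistic recalibration",
    )
    fit_i = sm.GLM(y, np.ones((n, 1)), family=sm.families.Binomial(),
                   offset=lp).fit()
    intercept = PerformanceEstimate(
        "calibration_intercept", float(fit_i.params[0]), float(fit_i.bse[0]), n,
        "offset convention (slope fixed at 1)",
    )
    return slope, intercept


def calibration_curve(observed_good, p_good, n_bins: int = 10) -> pd.DataFrame:
    """Equal-count binned calibration table.

    Columns: bin, p_mean (mean predicted), obs (observed proportion), n,
    ci_low/ci_high (Wilson binomial CI). Rows ordered by predicted mean;
    counts sum to n. If ties collapse the quantile edges the table carries
    fewer rows and ``degenerate`` is set on every row.
    """
    from statsmodels.stats.proportion import proportion_confint

    y = np.asarray(observed_good, dtype=float)
    p = np.asarray(p_good, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if y.size < n_bins:
        raise ValueError("fewer observations than bins")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    degenerate = edges.size < n_bins + 1
    if edges.size < 2:
        idx = np.zeros(y.size, dtype=int)
        n_eff = 1
    else:
        idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0,
                      edges.size - 2)
        n_eff = edges.size - 1
    rows = []
    for b in range(n_eff):
        m = idx == b
        k = int(m.sum())
        if k == 0:
            continue
        succ = y[m].sum()
        lo, hi = proportion_confint(succ, k, method="wilson")
        rows.append(
            {"bin": b, "p_mean": float(p[m].mean()), "obs": float(succ / k),
             "n": k, "ci_low": float(lo), "ci_high": float(hi),
             "degenerate": degenerate}
        )
    return pd.DataFrame(rows).sort_values("p_mean").reset_index(drop=True)
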