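"""Proportional-odds (common odds ratio) model for the ordinal mRS outcome.

Orientation: P(mRS <= k | x) = expit(alpha_k + x'beta), so a positive
coefficient — an odds ratio exp(beta) above 1 — means a better functional
outcome. Intercepts are optimized through a monotone parameterization
(alpha_0 plus positive increments), which guarantees nondecreasing
cumulative probabilities for every patient. Standard errors come from the
inverse observed information at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .design import DesignMatrix, ModelSpec, Term, build_design_matrix, resolve_spec

__all__ = [
    "FittedOrdinalModel",
    "fit_proportional_odds",
    "fit_model",
    "predict_distribution",
    "predict_good_outcome",
    "predict_benefit",
    "backward_eliminate",
    "likelihood_ratio_test",
    "summarize_effects",
]

GOOD_OUTCOME_MAX = 2  # "good functional outcome" = mRS 0-2


class FitError(RuntimeError):
    pass


class ContractError(ValueError):
    pass


def _nll_grad(params, X, cidx, K, w):
    """Negative log-likelihood and gradient in (alpha, beta) space.

    cidx is the category index (0..K-1) of each observation within the
    model's level set; alpha has length K-1.
    """
    alpha, beta = params[: K - 1], params[K - 1 :]
    eta = X @ beta
    top = cidx == K - 1
    bot = cidx == 0
    a_up = np.where(top, 0.0, alpha[np.minimum(cidx, K - 2)])
    a_lo = np.where(bot, 0.0, alpha[np.maximum(cidx - 1, 0)])
    gam_up = np.where(top, 1.0, expit(a_up + eta))
    gam_lo = np.where(bot, 0.0, expit(a_lo + eta))
    p = np.clip(gam_up - gam_lo, 1e-300, None)
    nll = -np.sum(w * np.log(p))

    g_up = np.where(top, 0.0, gam_up * (1 - gam_up))
    g_lo = np.where(bot, 0.0, gam_lo * (1 - gam_lo))
    deta = w * (g_up - g_lo) / p
    grad_beta = -(X.T @ deta)
    grad_alpha = np.zeros(K - 1)
    np.add.at(grad_alpha, np.minimum(cidx[~top], K - 2), -(w * g_up / p)[~top])
    np.add.at(grad_alpha, np.maximum(cidx[~bot] - 1, 0), (w * g_lo / p)[~bot])
    return nll, np.concatenate([grad_alpha, grad_beta])


def _theta_to_ab(theta, K):
    """Monotone parameterization: alpha_0 free, increments exp(delta)."""
    a = np.empty(K - 1)
    a[0] = theta[0]
    if K > 2:
        a[1:] = theta[0] + np.cumsum(np.exp(theta[1 : K - 1]))
    return np.concatenate([a, theta[K - 1 :]])


def _nll_grad_theta(theta, X, cidx, K, w):
    ab = _theta_to_ab(theta, K)
    nll, g = _nll_grad(ab, X, cidx, K, w)
    ga, gb = g[: K - 1], g[K - 1 :]
    gt = np.empty_like(theta)
    gt[0] = ga.sum()
    if K > 2:
        # d alpha_k / d delta_j = exp(delta_j) for k >= j
        tail = np.cumsum(ga[::-1])[::-1]
        gt[1 : K - 1] = np.exp(theta[1 : K - 1]) * tail[1:]
    gt[K - 1 :] = gb
    return nll, gt


def _fd_hessian(params, X, cidx, K, w, h=1e-5):
    """Observed information by central differences of the analytic gradient."""
    p = params.size
    H = np.empty((p, p))
    for j in range(p):
        step = h * max(1.0, abs(params[j]))
        up = params.copy()
        up[j] += step
        dn = params.copy()
        dn[j] -= step
        H[j] = (_nll_grad(up, X, cidx, K, w)[1] - _nll_grad(dn, X, cidx, K, w)[1]) / (
            2 * step
        )
    return (H + H.T) / 2


@dataclass
class FittedOrdinalModel:
    spec: ModelSpec | None
    labels: list[str]
    levels: np.ndarray  # sorted outcome levels the intercepts refer to
    alpha: np.ndarray  # cumulative-logit intercepts, length K-1
    beta: np.ndarray
    cov: np.ndarray  # covariance of (alpha, beta)
    loglik: float
    n: int
    converged: bool
    grad_norm: float
    separation: bool = False
    term_of_column: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return self.alpha.size + self.beta.size

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    def beta_se(self) -> np.ndarray:
        return self.se()[self.alpha.size :]

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.beta

    def good_cut_index(self) -> int:
        idx = int(np.sum(self.levels <= GOOD_OUTCOME_MAX)) - 1
        if idx < 0 or idx >= self.alpha.size:
            raise ContractError("good-outcome cut not identified by model levels")
        return idx

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict() if self.spec is not None else None,
            "labels": self.labels,
            "levels": self.levels.tolist(),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "n": self.n,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "separation": self.separation,
            "term_of_column": self.term_of_column,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedOrdinalModel":
        return cls(
            spec=ModelSpec.from_dict(d["spec"]) if d["spec"] else None,
            labels=list(d["labels"]),
            levels=np.asarray(d["levels"]),
            alpha=np.asarray(d["alpha"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            loglik=float(d["loglik"]),
            n=int(d["n"]),
            converged=bool(d["converged"]),
            grad_norm=float(d["grad_norm"]),
            separation=bool(d["separation"]),
            term_of_column=list(d["term_of_column"]),
        )


def fit_proportional_odds(
    X, y, weights=None, labels=None, spec=None, term_of_column=None,
    max_polish=50, gtol=1e-8,
) -> FittedOrdinalModel:
    """Maximum-likelihood fit of the cumulative-logit model.

    Columns are standardized internally for optimizer conditioning; the
    returned estimates and covariance are on the original scale. Raises
    FitError on non-convergence; flags (without raising) likely complete
    separation when a standardized coefficient runs away.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise ContractError("X and y length mismatch")
    levels = np.unique(y)
    K = levels.size
    if K < 2:
        raise ContractError("outcome has a single level")
    if n <= p + K - 1:
        raise ContractError("more parameters than observations")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    cidx = np.searchsorted(levels, y)

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    # start: empirical cumulative logits, zero slopes
    cum = np.cumsum(np.bincount(cidx, weights=w, minlength=K))[:-1] / w.sum()
    cum = np.clip(cum, 1e-4, 1 - 1e-4)
    a0 = logit(cum)
    incr = np.clip(np.diff(a0), 1e-4, None)
    theta0 = np.concatenate([[a0[0]], np.log(incr), np.zeros(p)])

    res = optimize.minimize(
        _nll_grad_theta, theta0, args=(Xs, cidx, K, w), jac=True, method="BFGS",
        options={"gtol": 1e-9, "maxiter": 500},
    )
    ab = _theta_to_ab(res.x, K)

    # Newton polish in (alpha, beta) space until gradient norm is tiny
    nll, g = _nll_grad(ab, Xs, cidx, K, w)
    for _ in range(max_polish):
        if np.max(np.abs(g)) < gtol:
            break
        H = _fd_hessian(ab, Xs, cidx, K, w)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(H.shape[0]), g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _half in range(30):
            cand = ab - t * step
            if np.all(np.diff(cand[: K - 1]) > 0) or K == 2:
                nll_c, g_c = _nll_grad(cand, Xs, cidx, K, w)
                if nll_c <= nll + 1e-12:
                    ab, nll, g = cand, nll_c, g_c
                    break
            t /= 2
        else:
            break

    grad_norm = float(np.max(np.abs(g)))
    converged = grad_norm < 1e-6
    if not converged:
        raise FitError(f"optimizer did not converge (max|grad| = {grad_norm:.2e})")

    separation = bool(np.any(np.abs(ab[K - 1 :]) > 15))
    if separation:
        warnings.warn("possible complete separation: coefficient capped estimate",
                      RuntimeWarning)

    # back to original scale
    beta_s = ab[K - 1 :]
    beta = beta_s / sd
    alpha = ab[: K - 1] - float(beta_s @ (mu / sd))

    params = np.concatenate([alpha, beta])
    H = _fd_hessian(params, X, cidx, K, w)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    cov = (cov + cov.T) / 2

    return FittedOrdinalModel(
        spec=spec,
        labels=list(labels) if labels is not None else [f"x{j}" for j in range(p)],
        levels=levels,
        alpha=alpha,
        beta=beta,
        cov=cov,
        loglik=float(-nll),
        n=n,
        converged=converged,
        grad_norm=grad_norm,
        separation=separation,
        term_of_column=list(term_of_column) if term_of_column else [],
    )


def fit_model(data: pd.DataFrame, spec: ModelSpec, weights=None) -> FittedOrdinalModel:
    """Resolve knots on the data, build the design matrix, and fit."""
    spec = resolve_spec(spec, data)
    dm = build_design_matrix(data, spec)
    y = np.asarray(data["mrs90"], dtype=int)
    return fit_proportional_odds(
        dm.X, y, weights=weights, labels=dm.labels, spec=spec,
        term_of_column=dm.term_of_column,
    )


def _design_for(model: FittedOrdinalModel, data: pd.DataFrame) -> DesignMatrix:
    if model.spec is None:
        raise ContractError("model carries no spec; pass a design matrix instead")
    dm = build_design_matrix(data, model.spec)
    if dm.labels != model.labels:
        raise ContractError("design columns do not match fitted model")
    return dm


def predict_distribution(model: FittedOrdinalModel, X) -> np.ndarray:
    """Per-patient probabilities over the model's outcome levels (rows sum to 1)."""
    if isinstance(X, pd.DataFrame):
        X = _design_for(model, X).X
    elif isinstance(X, DesignMatrix):
        if X.labels != model.labels:
            raise ContractError("design columns do not match fitted model")
        X = X.X
    eta = model.linear_predictor(X)
    K = model.levels.size
    cum = np.column_stack(
        [expit(a + eta) for a in model.alpha] + [np.ones_like(eta)]
    )
    probs = np.diff(np.column_stack([np.zeros_like(eta), cum]), axis=1)
    return probs


def predict_good_outcome(model: FittedOrdinalModel, X) -> np.ndarray:
    """P(mRS 0-2) per patient: expit(alpha_2 + eta)."""
    if isinstance(X, pd.DataFrame):
        X = _design_for(model, X).X
    elif isinstance(X, DesignMatrix):
        X = X.X
    eta = model.linear_predictor(X)
    return expit(model.alpha[model.good_cut_index()] + eta)


def predict_benefit(model: FittedOrdinalModel, data: pd.DataFrame) -> pd.DataFrame:
    """Counterfactual good-outcome probabilities and their difference.

    Evaluates P(mRS 0-2) with the treatment indicator (and every
    interaction involving it) set to 1, then 0, holding all other
    covariates fixed; benefit = p_good_evt - p_good_control.
    """
    if model.spec is None or not model.spec.has_treatment:
        raise ContractError("model spec has no treatment term")
    treated = data.copy()
    treated["evt"] = 1
    control = data.copy()
    control["evt"] = 0
    p1 = predict_good_outcome(model, treated)
    p0 = predict_good_outcome(model, control)
    return pd.DataFrame(
        {"p_good_evt": p1, "p_good_control": p0, "benefit": p1 - p0},
        index=data.index,
    )


def wald_joint_test(model: FittedOrdinalModel, stub: str) -> tuple[float, int, float]:
    """Joint Wald test that all columns of one term block are zero."""
    idx = [i for i, s in enumerate(model.term_of_column) if s == stub]
    if not idx:
        raise ContractError(f"term {stub!r} not in model")
    off = model.alpha.size
    b = model.beta[idx]
    V = model.cov[np.ix_([off + i for i in idx], [off + i for i in idx])]
    stat = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return stat, df, float(stats.chi2.sf(stat, df))


def backward_eliminate(
    spec: ModelSpec, data: pd.DataFrame, p_remove: float = 0.20,
    forced: tuple[str, ...] = (),
) -> tuple[ModelSpec, list[tuple[str, float]]]:
    """Backward elimination of weak predictors (joint Wald per variable).

    At each step the eligible variable with the largest p-value above
    ``p_remove`` is removed (all of its columns jointly); the treatment
    indicator, any variable interacting with it, and ``forced`` variables
    are never removed. Returns the reduced spec and the removal trace.
    """
    if not 0 < p_remove <= 1:
        raise ContractError("p_remove must be in (0, 1]")
    spec = resolve_spec(spec, data)
    trace: list[tuple[str, float]] = []
    while True:
        model = fit_model(data, spec)
        eligible = [v for v in spec.eliminable_variables() if v not in forced]
        if not eligible:
            break
        pvals = {v: wald_joint_test(model, v)[2] for v in eligible}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= p_remove:
            break
        trace.append((worst, pvals[worst]))
        spec = spec.drop_variable(worst)
    return spec, trace


def likelihood_ratio_test(
    full: FittedOrdinalModel, reduced: FittedOrdinalModel
) -> tuple[float, int, float]:
    """LRT of nested ordinal models fitted to the same rows."""
    if not set(reduced.labels) <= set(full.labels):
        raise ContractError("models are not nested (reduced columns not a subset)")
    if full.n != reduced.n:
        raise ContractError("models fitted to different numbers of rows")
    stat = 2 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise ContractError("full model has lower likelihood than reduced")
    stat = max(stat, 0.0)
    df = full.n_params - reduced.n_params
    if df == 0:
        return 0.0, 0, 1.0
    return float(stat), df, float(stats.chi2.sf(stat, df))


def summarize_effects(
    model: FittedOrdinalModel, piecewise_points: dict[str, float] | None = None
) -> pd.DataFrame:
    """Odds-ratio table with 95% Wald CIs.

    Linear and dummy terms: OR per (scaled) unit. Spline terms: two ORs per
    unit, the chord slopes of the fitted curve from the first knot to the
    inflection point and from the inflection point to the last knot
    (delta-method SEs). The inflection defaults to the middle knot.
    """
    piecewise_points = piecewise_points or {}
    off = model.alpha.size
    se = model.se()
    rows = []

    def wald_row(term, label, b, s):
        lo, hi = b - 1.959963984540054 * s, b + 1.959963984540054 * s
        rows.append(
            {"term": term, "label": label, "or": np.exp(b),
             "ci_low": np.exp(lo), "ci_high": np.exp(hi)}
        )

    spec = model.spec
    if spec is None:
        for j, lab in enumerate(model.labels):
            wald_row(lab, lab, model.beta[j], se[off + j])
        return pd.DataFrame(rows)

    for term in spec.terms:
        stub = term.label_stub()
        idx = [i for i, s_ in enumerate(model.term_of_column) if s_ == stub]
        if term.kind == "spline":
            knots = np.asarray(term.knots)
            mid = piecewise_points.get(term.variable, knots[len(knots) // 2])
            if not knots[0] < mid < knots[-1]:
                warnings.warn(
                    f"inflection {mid} outside knot span for {term.variable}",
                    RuntimeWarning,
                )
            from .design import rcs_basis

            Bk = rcs_basis(np.array([knots[0], mid, knots[-1]]), knots)
            for seg, (i0, i1) in (("below", (0, 1)), ("above", (1, 2))):
                c = (Bk[i1] - Bk[i0]) / (
                    [knots[0], mid, knots[-1]][i1] - [knots[0], mid, knots[-1]][i0]
                )
                b = float(c @ model.beta[idx])
                V = model.cov[np.ix_([off + i for i in idx], [off + i for i in idx])]
                s_ = float(np.sqrt(max(c @ V @ c, 0.0)))
                wald_row(stub, f"{term.variable}, per unit {seg} {mid:g}", b, s_)
        else:
            for i in idx:
                wald_row(stub, model.labels[i], model.beta[i], se[off + i])
    return pd.DataFrame(rows)
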