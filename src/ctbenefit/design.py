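"""Design-matrix construction from a declarative model specification.

Terms are linear columns, restricted (natural) cubic spline expansions,
reference-coded categorical dummies, and treatment-interaction products.
The spline basis follows the truncated-power natural-spline construction
with linearity enforced beyond the boundary knots and normalization by the
squared boundary-knot span, so coefficients stay on the variable's own
scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SplineSpec",
    "Term",
    "ModelSpec",
    "DesignMatrix",
    "rcs_basis",
    "default_knots",
    "build_design_matrix",
    "spline_coefficients_for_chord_slopes",
    "CATEGORY_LEVELS",
]

# Closed category sets; first level is the modelling reference.
CATEGORY_LEVELS = {
    "occlusion": ("ICA_ICAT", "M1", "M2"),
    "icac": ("NONE", "INTIMAL", "MEDIAL"),
}


class SpecError(ValueError):
    """Raised for invalid spline/model specifications."""


class DesignError(ValueError):
    """Raised when a cohort cannot be expanded under a spec (e.g. missing values)."""


def rcs_basis(x, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis, shape (n, K-1).

    Column 0 is ``x`` itself; columns 1..K-2 are the natural-spline
    truncated-power terms, divided by the squared span of the boundary
    knots. The represented function is linear outside the boundary knots
    and has continuous first and second derivatives everywhere.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 3:
        raise SpecError("restricted cubic spline needs at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise SpecError("knots must be strictly increasing")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    K = knots.size
    span2 = (knots[-1] - knots[0]) ** 2
    cols = [x]
    d_last = knots[-1] - knots[-2]
    for j in range(K - 2):
        t = np.clip(x - knots[j], 0.0, None) ** 3
        t -= np.clip(x - knots[-2], 0.0, None) ** 3 * (knots[-1] - knots[j]) / d_last
        t += np.clip(x - knots[-1], 0.0, None) ** 3 * (knots[-2] - knots[j]) / d_last
        cols.append(t / span2)
    return np.column_stack(cols)


def default_knots(values, k: int = 3, forced_middle: float | None = None) -> np.ndarray:
    """Knots at the 10th/50th/90th percentiles (k=3), middle optionally forced.

    For general k, knots are placed at equally spaced quantiles between the
    10th and 90th percentiles. A forced middle knot (e.g. a known inflection
    point such as a brain parenchymal fraction of 80%) replaces the median.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if np.unique(values).size < k:
        raise SpecError("degenerate sample: not enough distinct values for knots")
    qs = np.linspace(10, 90, k)
    knots = np.percentile(values, qs)
    if forced_middle is not None:
        knots[k // 2] = float(forced_middle)
    if np.any(np.diff(knots) <= 0):
        raise SpecError(f"knot placement degenerate: {knots}")
    return knots


def spline_coefficients_for_chord_slopes(
    knots: Sequence[float], slope_below: float, slope_above: float
) -> np.ndarray:
    """Coefficients (b1, b2) on a 3-knot basis matching two chord slopes.

    The chord slope of ``b1*x + b2*s(x)`` between knots 1-2 is set to
    ``slope_below`` and between knots 2-3 to ``slope_above``. Used by the
    synthetic generator to translate printed below/above-inflection odds
    ratios into a generating spline.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.size != 3:
        raise SpecError("chord-slope construction is defined for 3 knots")
    B = rcs_basis(knots, knots)  # basis at the knots, (3, 2)
    A = np.array(
        [
            (B[1] - B[0]) / (knots[1] - knots[0]),
            (B[2] - B[1]) / (knots[2] - knots[1]),
        ]
    )
    return np.linalg.solve(A, [slope_below, slope_above])


@dataclass(frozen=True)
class SplineSpec:
    variable: str
    knots: tuple[float, ...]
    scale: float = 1.0

    def __post_init__(self):
        if len(self.knots) < 3 or np.any(np.diff(self.knots) <= 0):
            raise SpecError(f"invalid knots for {self.variable}: {self.knots}")


@dataclass(frozen=True)
class Term:
    """One model term.

    kind: 'linear' | 'spline' | 'categorical' | 'treatment' | 'interaction'.
    ``scale`` divides the raw variable first (e.g. 5.0 for per-5-mL volumes,
    30.0 for per-30-min times). For 'interaction', ``with_variable`` names
    the main-effect variable multiplied with the treatment indicator.
    """

    kind: str
    variable: str
    scale: float = 1.0
    knots: tuple[float, ...] | None = None
    forced_middle: float | None = None
    with_variable: str | None = None

    def label_stub(self) -> str:
        if self.kind == "interaction":
            return f"evt:{self.with_variable}"
        return self.variable


@dataclass
class ModelSpec:
    """Ordered term list defining a design matrix."""

    name: str
    terms: list[Term] = field(default_factory=list)

    @property
    def has_treatment(self) -> bool:
        return any(t.kind == "treatment" for t in self.terms)

    def variables(self) -> list[str]:
        out = []
        for t in self.terms:
            v = t.with_variable if t.kind == "interaction" else t.variable
            if v not in out:
                out.append(v)
        return out

    def eliminable_variables(self) -> list[str]:
        """Variables eligible for backward elimination: everything except the
        treatment indicator and variables tied to it through an interaction."""
        protected = {"evt"}
        protected.update(
            t.with_variable for t in self.terms if t.kind == "interaction"
        )
        return [
            t.variable
            for t in self.terms
            if t.kind in ("linear", "spline", "categorical")
            and t.variable not in protected
        ]

    def drop_variable(self, variable: str) -> "ModelSpec":
        terms = [
            t
            for t in self.terms
            if not (
                t.kind in ("linear", "spline", "categorical")
                and t.variable == variable
            )
        ]
        if len(terms) == len(self.terms):
            raise SpecError(f"variable {variable!r} not in spec {self.name!r}")
        return ModelSpec(name=self.name, terms=terms)

    def with_terms(self, extra: Sequence[Term], name: str | None = None) -> "ModelSpec":
        existing = {t.variable for t in self.terms if t.kind != "interaction"}
        for t in extra:
            if t.kind != "interaction" and t.variable in existing:
                raise SpecError(f"variable {t.variable!r} already in spec")
        return ModelSpec(name=name or self.name, terms=[*self.terms, *extra])

    # ---- JSON (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "terms": [
                {k: v for k, v in vars(t).items() if v not in (None,)}
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        terms = []
        for td in d["terms"]:
            td = dict(td)
            if "knots" in td and td["knots"] is not None:
                td["knots"] = tuple(td["knots"])
            terms.append(Term(**td))
        return cls(name=d["name"], terms=terms)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DesignMatrix:
    X: np.ndarray
    labels: list[str]
    term_of_column: list[str]  # term stub per column, for joint Wald blocks
    spec: ModelSpec

    @property
    def shape(self):
        return self.X.shape

    def columns_of(self, stub: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.term_of_column) if s == stub]
        if not idx:
            raise SpecError(f"no columns for term {stub!r}")
        return np.asarray(idx)


def resolve_spec(spec: ModelSpec, data: pd.DataFrame) -> ModelSpec:
    """Fill in data-driven knots for spline terms that carry none.

    Knots default to the 10th/50th/90th percentiles of the (scaled) sample,
    with any forced middle knot honoured.
    """
    terms = []
    for t in spec.terms:
        if t.kind == "spline" and t.knots is None:
            vals = np.asarray(data[t.variable], dtype=float) / t.scale
            knots = default_knots(vals[~np.isnan(vals)], 3, t.forced_middle)
            t = Term(
                kind="spline",
                variable=t.variable,
                scale=t.scale,
                knots=tuple(knots),
                forced_middle=t.forced_middle,
            )
        terms.append(t)
    return ModelSpec(name=spec.name, terms=terms)


def _term_columns(term: Term, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    if term.kind == "treatment":
        col = np.asarray(data["evt"], dtype=float)
        return col[:, None], ["evt"]
    if term.kind == "interaction":
        base, labels = _term_columns(
            Term(kind="linear", variable=term.with_variable, scale=term.scale), data
        )
        evt = np.asarray(data["evt"], dtype=float)[:, None]
        return base * evt, [f"evt:{lab}" for lab in labels]
    raw = data[term.variable]
    if term.kind == "categorical":
        levels = CATEGORY_LEVELS[term.variable]
        vals = raw.astype(str).to_numpy()
        unknown = set(vals) - set(levels)
        if unknown:
            raise DesignError(f"{term.variable}: unknown levels {sorted(unknown)}")
        cols = np.column_stack([(vals == lev).astype(float) for lev in levels[1:]])
        return cols, [f"{term.variable}[{lev}]" for lev in levels[1:]]
    x = np.asarray(raw, dtype=float) / term.scale
    if term.kind == "linear":
        return x[:, None], [term.variable]
    if term.kind == "spline":
        if term.knots is None:
            raise SpecError(
                f"spline term {term.variable!r} has no knots; resolve_spec first"
            )
        B = rcs_basis(x, term.knots)
        labels = [term.variable] + [
            term.variable + "'" * (j + 1) for j in range(B.shape[1] - 1)
        ]
        return B, labels
    raise SpecError(f"unknown term kind {term.kind!r}")


def build_design_matrix(data: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Expand a complete cohort table into the numeric design matrix.

    Raises DesignError naming patient and variable on any missing value
    among referenced covariates (imputation must precede design).
    """
    spec = resolve_spec(spec, data)
    blocks, labels, stubs = [], [], []
    for term in spec.terms:
        var = term.with_variable if term.kind == "interaction" else term.variable
        if var not in data.columns:
            raise DesignError(f"variable {var!r} not in data")
        missing = data[var].isna()
        if missing.any():
            pid = data.index[missing][0]
            if "patient_id" in data.columns:
                pid = data.loc[missing, "patient_id"].iloc[0]
            raise DesignError(f"missing value for {var!r} (patient {pid})")
        cols, labs = _term_columns(term, data)
        blocks.append(cols)
        labels.extend(labs)
        stubs.extend([term.label_stub()] * cols.shape[1])
    X = np.column_stack(blocks) if blocks else np.empty((len(data), 0))
    return DesignMatrix(X=X, labels=labels, term_of_column=stubs, spec=spec)
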