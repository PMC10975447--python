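"""Central composite design, response-surface OLS, and correlation analysis.

The flowability study design crosses three numeric factors — particle size
(x1, 725 ± 375 μm), moisture content (x2, 2 ± 1 %), and glidant/lubricant
ratio (x3, already coded) — with one two-level categorical factor, particle
class (x4: granule −1, pellet +1).  Each categorical block holds a 2^(3−1)
half-fraction (defining relation I = −x1·x2·x3), six axial runs, and two
center points: 12 runs per block, 24 in total.

Factors enter all models in coded units, ``(actual − center) / step``, so
factorial levels map to ±1 and coefficients are effects per coded unit.
Because the categorical column is orthogonal to every other model column in
this design, its coefficient always equals half the pellet-minus-granule
mean difference, whatever the model form — a useful arithmetic cross-check.

Model fitting is ordinary least squares with per-term t-tests, an overall
F-test, R², and PRESS-based predicted R²; model reduction is backward
elimination at a configurable significance level, preserving hierarchy.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FACTOR_NAMES",
    "load_design",
    "load_saor_ft",
    "load_avalanche",
    "load_fit_params",
    "load_study_responses",
    "code_factor",
    "build_ccd",
    "term_column",
    "model_terms",
    "ResponseSurfaceRegressor",
    "ResponseSurfaceModel",
    "CorrelationMatrix",
    "fit_response_surface",
    "reduce_model",
    "pearson_matrix",
]

FACTOR_NAMES = ("x1", "x2", "x3", "x4")

# coding of the packaged design: (actual column, center, step)
_CODING = {
    "x1": ("particle_size_um", 725.0, 375.0),
    "x2": ("moisture_pct", 2.0, 1.0),
    "x3": ("glidant_code", 0.0, 1.0),  # already coded in the design table
    "x4": ("particle_class", 0.0, 1.0),
}


def _read_fixture(name: str, n_rows: int = 24) -> pd.DataFrame:
    with resources.files("pileflow.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh)
    if len(df) != n_rows:
        raise ValueError(f"fixture {name} must have {n_rows} rows, got {len(df)}")
    return df


def load_design(coded: bool = True) -> pd.DataFrame:
    """The 24-run study design; with ``coded=True`` adds columns x1..x4."""
    df = _read_fixture("table1_design.csv")
    if coded:
        for name, (col, center, step) in _CODING.items():
            df[name] = code_factor(df[col].to_numpy(float), center, step)
    return df


def load_saor_ft() -> pd.DataFrame:
    """Static angle of repose (deg) and flow time (s) per run."""
    return _read_fixture("table3_saor_ft.csv")


def load_avalanche() -> pd.DataFrame:
    """Avalanche amplitude (px), wavelength (frames), and count per run."""
    return _read_fixture("table4_avalanche.csv")


def load_fit_params() -> pd.DataFrame:
    """Power-law fit parameters a, b, c, a+b and AUFC per run."""
    return _read_fixture("table5_fit_params.csv")


def load_study_responses() -> pd.DataFrame:
    """All measured responses joined on sample, in correlation-table order."""
    t3, t4, t5 = load_saor_ft(), load_avalanche(), load_fit_params()
    df = t5.merge(t4, on="sample").merge(t3, on="sample")
    return df[
        [
            "sample",
            "a",
            "b",
            "c",
            "aufc",
            "a_plus_b",
            "wavelength_frames",
            "amplitude_px",
            "count",
            "saor_deg",
            "ft_s",
        ]
    ]


def code_factor(actual, center: float, step: float):
    """Coded level ``(actual - center) / step``; factorial levels map to ±1."""
    if step == 0:
        raise ValueError("coding step must be nonzero")
    return (np.asarray(actual, dtype=float) - center) / step


def build_ccd(
    n_numeric: int = 3,
    axial: float = 1.4,
    categorical_levels: tuple[float, ...] = (-1.0, 1.0),
    fraction: str = "half",
    n_center: int = 2,
) -> pd.DataFrame:
    """Coded central composite design, replicated per categorical level.

    ``fraction="half"`` uses the 2^(k−1) fraction with defining relation
    ``I = -x1·x2·...·xk`` (the study layout: 4 + 6 + 2 = 12 runs per
    block); ``fraction="full"`` uses all 2^k factorial corners.  Axial runs
    sit at ±``axial`` on one factor at a time; ``n_center`` center points
    close each block.
    """
    if axial <= 1:
        raise ValueError("axial distance must exceed 1")
    if fraction not in ("half", "full"):
        raise ValueError("fraction must be 'half' or 'full'")
    corners = np.array(list(itertools.product((-1.0, 1.0), repeat=n_numeric)))
    if fraction == "half":
        corners = corners[np.prod(corners, axis=1) < 0]
    axial_runs = []
    for j in range(n_numeric):
        for s in (-1.0, 1.0):
            run = np.zeros(n_numeric)
            run[j] = s * axial
            axial_runs.append(run)
    block = np.vstack([corners, axial_runs, np.zeros((n_center, n_numeric))])

    rows = []
    for level in categorical_levels:
        for run in block:
            rows.append(list(run) + [level])
    cols = [f"x{j + 1}" for j in range(n_numeric)] + [f"x{n_numeric + 1}"]
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "sample", np.arange(1, len(df) + 1))
    return df


_TERM_RE = re.compile(r"^(x\d+)(?::(x\d+)|\^2)?$")


def term_column(design: pd.DataFrame, term: str) -> np.ndarray:
    """Numeric column of a model term evaluated on coded factors.

    Terms: ``"Intercept"`` (or ``"1"``), main effects ``"x1"``,
    interactions ``"x1:x2"``, and squares ``"x1^2"``.
    """
    n = len(design)
    if term in ("Intercept", "intercept", "1"):
        return np.ones(n)
    m = _TERM_RE.match(term)
    if m is None or m.group(1) not in design.columns:
        raise ValueError(f"unknown model term {term!r}")
    col = design[m.group(1)].to_numpy(float)
    if term.endswith("^2"):
        return col**2
    if m.group(2) is not None:
        if m.group(2) not in design.columns:
            raise ValueError(f"unknown model term {term!r}")
        return col * design[m.group(2)].to_numpy(float)
    return col


def model_terms(
    form: str,
    factors: tuple[str, ...] = FACTOR_NAMES,
    categorical: tuple[str, ...] = ("x4",),
) -> list[str]:
    """Ordered term list of a response-surface model form.

    ``"linear"``: intercept + main effects; ``"2fi"`` adds all two-factor
    interactions; ``"quadratic"`` adds squares of the numeric factors only
    (the square of a ±1 categorical factor is aliased with the intercept).
    """
    form = form.lower()
    if form not in ("linear", "2fi", "quadratic"):
        raise ValueError(f"unknown model form {form!r}")
    terms = ["Intercept"] + list(factors)
    if form in ("2fi", "quadratic"):
        terms += [f"{a}:{b}" for a, b in itertools.combinations(factors, 2)]
    if form == "quadratic":
        terms += [f"{f}^2" for f in factors if f not in categorical]
    return terms


def _involved(term: str) -> set[str]:
    if term == "Intercept":
        return set()
    return set(re.findall(r"x\d+", term))


class ResponseSurfaceRegressor(RegressorMixin, BaseEstimator):
    """OLS response-surface model on coded CCD factors.

    scikit-learn style estimator: ``fit(X, y)`` with ``X`` a DataFrame of
    coded factor columns (x1..x4), ``predict(X)`` evaluates the surface.
    The model matrix is built from ``terms`` if given, else from ``form``.

    Attributes (after fit)
    ----------------------
    terms_ : list of str
        Model terms in matrix order, intercept first.
    coef_ : ndarray
        Coefficients per term (response units per coded unit).
    stderr_, tvalues_, pvalues_ : ndarray
        Per-term standard errors, t statistics, and two-sided p-values on
        the residual degrees of freedom.
    f_pvalue_ : float
        Overall model F-test p-value.
    r_squared_, predicted_r_squared_ : float
        R² and PRESS-based (leave-one-out) predicted R²; the latter can be
        negative when the model predicts worse than the response mean.
    """

    def __init__(self, form: str = "linear", terms: list[str] | None = None):
        self.form = form
        self.terms = terms

    def _design_matrix(self, X: pd.DataFrame, terms: list[str]) -> np.ndarray:
        return np.column_stack([term_column(X, t) for t in terms])

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        terms = list(self.terms) if self.terms is not None else model_terms(
            self.form, factors=tuple(c for c in FACTOR_NAMES if c in X.columns)
        )
        if len(y) != len(X):
            raise ValueError("response length must match run count")
        if len(y) < len(terms) + 1:
            raise ValueError(
                f"{len(terms)} terms need more than {len(y)} runs to fit"
            )
        M = self._design_matrix(X, terms)
        rank = np.linalg.matrix_rank(M)
        if rank < M.shape[1]:
            raise ValueError(
                f"rank-deficient model matrix (rank {rank} < {M.shape[1]}): "
                "aliased terms among " + ", ".join(terms)
            )
        ols = sm.OLS(y, M).fit()
        self.terms_ = terms
        self.coef_ = ols.params
        self.stderr_ = ols.bse
        self.tvalues_ = ols.tvalues
        self.pvalues_ = ols.pvalues
        self.f_pvalue_ = float(ols.f_pvalue)
        self.r_squared_ = float(ols.rsquared)
        # PRESS / predicted R² via the leave-one-out closed form
        hat = ols.get_influence().hat_matrix_diag
        press = float(np.sum((ols.resid / (1.0 - hat)) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        self.predicted_r_squared_ = 1.0 - press / sst if sst > 0 else float("nan")
        self.press_ = press
        self._ols_result = ols
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame):
        check_is_fitted(self, "coef_")
        return self._design_matrix(X, self.terms_) @ self.coef_


@dataclass(frozen=True)
class ResponseSurfaceModel:
    """Fitted response surface: terms, coefficients, and diagnostics."""

    form: str
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    stderr: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    f_pvalue: float
    r_squared: float
    predicted_r_squared: float
    _design: pd.DataFrame = field(repr=False, compare=False, default=None)
    _response: np.ndarray = field(repr=False, compare=False, default=None)

    def coef(self, term: str) -> float:
        return self.coefficients[term]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "coefficient": [self.coefficients[t] for t in self.terms],
                "stderr": [self.stderr[t] for t in self.terms],
                "t": [self.tvalues[t] for t in self.terms],
                "p_value": [self.pvalues[t] for t in self.terms],
            }
        )


def fit_response_surface(
    design: pd.DataFrame,
    response,
    form: str = "linear",
    terms: list[str] | None = None,
) -> ResponseSurfaceModel:
    """Fit a linear / 2FI / quadratic response surface on coded factors."""
    reg = ResponseSurfaceRegressor(form=form, terms=terms).fit(design, response)
    return ResponseSurfaceModel(
        form=form if terms is None else "custom",
        terms=tuple(reg.terms_),
        coefficients=dict(zip(reg.terms_, map(float, reg.coef_))),
        stderr=dict(zip(reg.terms_, map(float, reg.stderr_))),
        tvalues=dict(zip(reg.terms_, map(float, reg.tvalues_))),
        pvalues=dict(zip(reg.terms_, map(float, reg.pvalues_))),
        f_pvalue=reg.f_pvalue_,
        r_squared=reg.r_squared_,
        predicted_r_squared=reg.predicted_r_squared_,
        _design=design,
        _response=np.asarray(response, dtype=float),
    )


def reduce_model(
    model: ResponseSurfaceModel, alpha: float = 0.05
) -> ResponseSurfaceModel:
    """Backward elimination of non-significant terms, preserving hierarchy.

    Repeatedly drops the term with the largest p-value above ``alpha`` and
    refits.  A main effect is kept while any of its interactions or its
    square remain in the model; the intercept is always kept.
    """
    current = model
    while True:
        live = list(current.terms)
        removable = []
        for t in live:
            if t == "Intercept":
                continue
            if _TERM_RE.match(t) and ":" not in t and "^" not in t:
                # main effect: protected while a higher-order term uses it
                if any(
                    t in _involved(o) and o != t for o in live
                ):
                    continue
            if current.pvalues[t] > alpha:
                removable.append(t)
        if not removable:
            return current
        worst = max(removable, key=lambda t: current.pvalues[t])
        new_terms = [t for t in live if t != worst]
        current = fit_response_surface(
            current._design, current._response, terms=new_terms
        )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson correlations with two-tailed p-values."""

    names: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def stars(self, i: str, j: str) -> str:
        p = self.p.loc[i, j]
        if not np.isfinite(p):
            return ""
        return "**" if p < 0.01 else "*" if p < 0.05 else ""


def pearson_matrix(columns: pd.DataFrame) -> CorrelationMatrix:
    """Pearson r and two-tailed t-test p-values for every column pair.

    Zero-variance columns yield NaN entries with a warning rather than a
    silent zero.  Requires at least 3 complete rows.
    """
    df = pd.DataFrame(columns)
    if len(df) < 3:
        raise ValueError("need at least 3 rows for correlation")
    names = tuple(df.columns)
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        xi, xj = df.iloc[:, i].to_numpy(float), df.iloc[:, j].to_numpy(float)
        if np.std(xi) == 0 or np.std(xj) == 0:
            warnings.warn(
                f"zero variance in {names[i]!r} or {names[j]!r}: "
                "correlation undefined"
            )
            r[i, j] = r[j, i] = np.nan
            p[i, j] = p[j, i] = np.nan
            continue
        res = stats.pearsonr(xi, xj)
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
    return CorrelationMatrix(
        names=names,
        r=pd.DataFrame(r, index=names, columns=names),
        p=pd.DataFrame(p, index=names, columns=names),
        n=len(df),
    )
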