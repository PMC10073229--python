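"""Normalisation and group statistics for per-cell lipid data.

The analysis pattern mirrors the standard R workflow for nested ecological
designs (cells within colonies within species):

1. normalise each variable to the mean of the species' endosymbiotic cells,
   making species comparable on a common relative scale;
2. check normality (Shapiro-Wilk) and homoscedasticity (Levene,
   median-centred i.e. Brown-Forsythe) and log/sqrt-transform if needed;
3. compare cell types with a linear mixed model — fixed cell-type effect,
   random colony intercept, REML estimation — with Satterthwaite
   denominator degrees of freedom for t tests of the fixed effects;
4. compare candidate fixed-effect structures by BIC on ML fits.

The mixed model here is the single-random-intercept case

    y = X beta + Z u + eps,   u ~ N(0, sigma_c^2 I),  eps ~ N(0, sigma_e^2 I)

for which the REML criterion profiles down to a 1-D optimisation over the
variance ratio lambda = sigma_c^2 / sigma_e^2; the fit is exact and fast.
Satterthwaite df follow lmerTest's recipe: df = 2 f^2 / (g' A g) with
f the sampling variance of the coefficient, g its gradient with respect to
the variance components, and A the inverse observed information of the REML
criterion (both obtained numerically).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps

logger = logging.getLogger(__name__)

REL_PREFIX = "rel_"
DEFAULT_VARIABLES = ("lpo_ratio", "lipid_volume_um3")


# --------------------------------------------------------------------------
# normalisation, assumptions, transforms
# --------------------------------------------------------------------------


def normalise_to_endosymbiont_mean(
    table: pd.DataFrame,
    variables: tuple[str, ...] = DEFAULT_VARIABLES,
    species_col: str = "species",
    celltype_col: str = "cell_type",
    reference_type: str = "endosymbiotic",
) -> pd.DataFrame:
    """Divide each variable by the species' endosymbiotic-cell mean.

    Adds ``rel_<variable>`` columns; within each species the mean of a
    relative variable over its endosymbiotic cells is exactly 1. Raises if a
    species has no endosymbiotic cells with finite values.
    """
    out = table.copy()
    for var in variables:
        out[REL_PREFIX + var] = np.nan
    for species, group in table.groupby(species_col, sort=False):
        ref = group[group[celltype_col] == reference_type]
        for var in variables:
            ref_vals = ref[var].dropna()
            if len(ref_vals) == 0 or not np.isfinite(ref_vals.mean()):
                raise ValueError(
                    f"species {species!r} has no {reference_type} cells with "
                    f"finite {var!r}; cannot normalise"
                )
            mean = ref_vals.mean()
            if mean == 0:
                raise ValueError(f"{reference_type} mean of {var!r} is zero for {species!r}")
            out.loc[group.index, REL_PREFIX + var] = group[var] / mean
    return out


@dataclass
class AssumptionReport:
    shapiro_w: float
    shapiro_p: float
    levene_f: float
    levene_p: float

    @property
    def normal(self) -> bool:
        return self.shapiro_p >= 0.05

    @property
    def homoscedastic(self) -> bool:
        return self.levene_p >= 0.05


def check_assumptions(values, groups) -> AssumptionReport:
    """Shapiro-Wilk on the pooled values and Brown-Forsythe (median-centred
    Levene) across groups. Requires >= 3 observations per group; constant
    input is rejected because both tests are undefined for it."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if np.ptp(values) == 0:
        raise ValueError("values are constant; normality/variance tests undefined")
    samples = [values[groups == g] for g in pd.unique(groups)]
    if any(len(s) < 3 for s in samples):
        raise ValueError("each group needs at least 3 observations")
    sw, sp = sps.shapiro(values)
    lf, lp = sps.levene(*samples, center="median")
    return AssumptionReport(float(sw), float(sp), float(lf), float(lp))


def transform(values, kind: str = "none"):
    """Elementwise log / sqrt / identity transform of an array or Series."""
    arr = np.asarray(values, dtype=float)
    if kind == "none":
        return arr.copy()
    if kind == "log":
        bad = np.flatnonzero(arr <= 0)
        if bad.size:
            raise ValueError(
                f"log transform requires strictly positive input; offending "
                f"row indices: {bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
            )
        return np.log(arr)
    if kind == "sqrt":
        if (arr < 0).any():
            raise ValueError("sqrt transform requires non-negative input")
        return np.sqrt(arr)
    raise ValueError(f"unknown transform {kind!r}; expected log, sqrt or none")


# --------------------------------------------------------------------------
# REML random-intercept model with Satterthwaite df
# --------------------------------------------------------------------------


@dataclass
class MixedModelResult:
    """REML fit of y = X beta + (colony intercept) + residual."""

    terms: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    dfs: np.ndarray  # Satterthwaite denominator df per coefficient
    p_values: np.ndarray
    sigma2_colony: float
    sigma2_residual: float
    reml_loglik: float
    boundary: bool  # colony variance estimated at the zero boundary
    n_obs: int
    n_groups: int
    mode: str = "per_cell"

    def coef(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "estimate": float(self.estimates[i]),
            "se": float(self.std_errors[i]),
            "t": float(self.t_values[i]),
            "df": float(self.dfs[i]),
            "p": float(self.p_values[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "se": self.std_errors,
                "t": self.t_values,
                "df": self.dfs,
                "p": self.p_values,
            }
        )


def build_design(
    data: pd.DataFrame, fixed_effects: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + dummy-coded categoricals (first level, sorted, as
    reference) + numeric covariates, in the order given."""
    n = len(data)
    columns: list[np.ndarray] = [np.ones(n)]
    names = ["(Intercept)"]
    for col in fixed_effects:
        series = data[col]
        if series.dtype.kind in "OUSb" or isinstance(series.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(series.astype(str)))
            for level in levels[1:]:
                columns.append((series.astype(str) == level).to_numpy(float))
                names.append(f"{col}[{level}]")
        else:
            columns.append(series.to_numpy(float))
            names.append(col)
    X = np.column_stack(columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix is rank-deficient for fixed effects {fixed_effects}")
    return X, names


def _reml_pieces(theta: np.ndarray, X: np.ndarray, y: np.ndarray, Z: np.ndarray):
    """REML loglik (up to an additive constant) and the fixed-effect GLS
    pieces at variance components theta = (sigma2_colony, sigma2_residual)."""
    s2c, s2e = theta
    n, p = X.shape
    V = s2e * np.eye(n) + s2c * (Z @ Z.T)
    cho = np.linalg.cholesky(V)
    logdetV = 2.0 * np.log(np.diag(cho)).sum()
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    XtViX = X.T @ Vi_X
    C = np.linalg.inv(XtViX)
    beta = C @ (X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    ll = -0.5 * (logdetV + logdetXtViX + quad)
    return ll, beta, C


def fit_mixed_model(
    data: pd.DataFrame,
    response: str,
    fixed_effects: list[str] | str = "cell_type",
    group_col: str = "colony",
    mode: str = "per_cell",
) -> MixedModelResult:
    """Fit the REML linear mixed model with a random colony intercept.

    Parameters
    ----------
    data
        Per-cell (or per-colony) table.
    response
        Response column (already transformed if a transform was needed).
    fixed_effects
        Fixed-effect column names; categoricals are dummy coded.
    group_col
        Grouping column for the random intercept.
    mode
        ``"per_cell"`` fits the model to individual cells (default);
        ``"colony_mean"`` first averages the response within colony x
        fixed-effect combination and fits the model to those means — the
        "mean colony values" reading of the standard workflow.

    Notes
    -----
    The REML criterion is profiled over lambda = sigma_c^2/sigma_e^2 and
    optimised by bounded scalar search, so the fit is deterministic. When
    the colony variance is estimated at the zero boundary the result is
    flagged and the t tests reduce exactly to OLS with n - p df.
    """
    if isinstance(fixed_effects, str):
        fixed_effects = [fixed_effects]
    work = data.dropna(subset=[response]).copy()
    if mode == "colony_mean":
        cats = [
            c
            for c in fixed_effects
            if work[c].dtype.kind in "OUSb" or isinstance(work[c].dtype, pd.CategoricalDtype)
        ]
        nums = [c for c in fixed_effects if c not in cats]
        agg = {response: "mean", **{c: "mean" for c in nums}}
        work = work.groupby([group_col, *cats], as_index=False, sort=True).agg(agg)
    elif mode != "per_cell":
        raise ValueError(f"mode must be 'per_cell' or 'colony_mean', got {mode!r}")

    groups = pd.unique(work[group_col])
    if len(groups) < 2:
        raise ValueError("need at least 2 colonies for a random colony intercept")
    X, names = build_design(work, fixed_effects)
    y = work[response].to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than observations")
    Z = (work[group_col].to_numpy()[:, None] == np.asarray(groups)[None, :]).astype(float)

    # ---- profile REML over lambda = s2c/s2e --------------------------------
    def neg_profile(log_lam: float) -> float:
        lam = math.exp(log_lam)
        V0 = np.eye(n) + lam * (Z @ Z.T)
        Vi_X = np.linalg.solve(V0, X)
        Vi_y = np.linalg.solve(V0, y)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        quad = float(r @ np.linalg.solve(V0, r))
        s2e = quad / (n - p)
        sign, logdetV0 = np.linalg.slogdet(V0)
        _, logdetXtViX = np.linalg.slogdet(XtViX)
        # ln|V| = n ln s2e + ln|V0|; ln|X'V^-1X| = ln|XtViX| - p ln s2e
        return 0.5 * (
            logdetV0 + logdetXtViX + (n - p) * math.log(s2e) + (n - p)
        )

    grid = np.linspace(-12.0, 8.0, 41)
    vals = [neg_profile(g) for g in grid]
    i0 = int(np.argmin(vals))
    lo, hi = grid[max(i0 - 1, 0)], grid[min(i0 + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_profile, bounds=(lo, hi), method="bounded")
    lam = math.exp(res.x)
    # compare against the boundary lambda -> 0 (OLS)
    boundary = neg_profile(-30.0) <= res.fun + 1e-10 or lam < 1e-8
    if boundary:
        lam = 0.0

    V0 = np.eye(n) + lam * (Z @ Z.T)
    Vi_X = np.linalg.solve(V0, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ np.linalg.solve(V0, y))
    r = y - X @ beta
    s2e = float(r @ np.linalg.solve(V0, r)) / (n - p)
    s2c = lam * s2e
    theta = np.array([s2c, s2e])
    ll, _, C = _reml_pieces(theta, X, y, Z)
    se = np.sqrt(s2e * np.diag(np.linalg.inv(XtViX)))
    tvals = beta / se

    # ---- Satterthwaite df --------------------------------------------------
    if boundary:
        dfs = np.full(p, float(n - p))
    else:
        dfs = _satterthwaite_dfs(theta, X, y, Z)
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dfs)

    return MixedModelResult(
        terms=names,
        estimates=beta,
        std_errors=se,
        t_values=tvals,
        dfs=dfs,
        p_values=pvals,
        sigma2_colony=s2c,
        sigma2_residual=s2e,
        reml_loglik=float(ll - 0.5 * (n - p) * math.log(2 * math.pi)),
        boundary=bool(boundary),
        n_obs=n,
        n_groups=len(groups),
        mode=mode,
    )


def _satterthwaite_dfs(
    theta: np.ndarray, X: np.ndarray, y: np.ndarray, Z: np.ndarray
) -> np.ndarray:
    """Per-coefficient Satterthwaite denominator df.

    df_j = 2 f_j(theta)^2 / (g_j' A g_j), with f_j the j-th diagonal of the
    GLS coefficient covariance, g_j its numerical gradient in theta, and A
    the inverse observed information of the REML log-likelihood.
    """
    p = X.shape[1]

    def covdiag(th: np.ndarray) -> np.ndarray:
        _, _, C = _reml_pieces(th, X, y, Z)
        return np.diag(C).copy()

    def loglik(th: np.ndarray) -> float:
        return _reml_pieces(th, X, y, Z)[0]

    h = np.maximum(1e-4 * np.abs(theta), 1e-7)
    # gradient of each covariance diagonal (central differences)
    grads = np.zeros((2, p))
    for k in range(2):
        e = np.zeros(2)
        e[k] = h[k]
        grads[k] = (covdiag(theta + e) - covdiag(theta - e)) / (2 * h[k])
    # observed information (negative Hessian of REML loglik)
    H = np.zeros((2, 2))
    for k in range(2):
        for l in range(k, 2):
            ek = np.zeros(2)
            el = np.zeros(2)
            ek[k] = h[k]
            el[l] = h[l]
            H[k, l] = H[l, k] = (
                loglik(theta + ek + el)
                - loglik(theta + ek - el)
                - loglik(theta - ek + el)
                + loglik(theta - ek - el)
            ) / (4 * h[k] * h[l])
    A = np.linalg.inv(-H)
    f = covdiag(theta)
    dfs = np.empty(p)
    for j in range(p):
        g = grads[:, j]
        denom = float(g @ A @ g)
        dfs[j] = 2.0 * f[j] ** 2 / denom if denom > 0 else float(len(y) - p)
    return dfs


# --------------------------------------------------------------------------
# BIC model comparison
# --------------------------------------------------------------------------


@dataclass
class ModelComparison:
    candidates: list[tuple[str, ...]]
    logliks: list[float]
    bics: list[float]
    n_obs: int
    best_index: int = field(init=False)

    def __post_init__(self) -> None:
        self.best_index = int(np.argmin(self.bics))

    @property
    def best_model(self) -> tuple[str, ...]:
        return self.candidates[self.best_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictors": [" + ".join(c) if c else "(intercept)" for c in self.candidates],
                "loglik": self.logliks,
                "bic": self.bics,
                "best": [i == self.best_index for i in range(len(self.candidates))],
            }
        )


def compare_models_bic(
    data: pd.DataFrame,
    response: str,
    candidate_predictor_sets: list[tuple[str, ...]],
) -> ModelComparison:
    """Rank candidate fixed-effect structures by BIC on ML (OLS) fits.

    All candidates are fit to the identical complete-case rows of the union
    of predictors, so likelihoods are comparable. BIC = -2 loglik + k ln n
    with k counting the mean parameters plus the error variance.
    """
    if not candidate_predictor_sets:
        raise ValueError("need at least one candidate predictor set")
    all_cols = {response}
    for cand in candidate_predictor_sets:
        all_cols.update(cand)
    work = data.dropna(subset=sorted(all_cols))
    n = len(work)
    if n < 3:
        raise ValueError("too few complete-case rows for model comparison")
    y = work[response].to_numpy(float)
    logliks, bics = [], []
    for cand in candidate_predictor_sets:
        X, _ = build_design(work, list(cand))
        fit = sm.OLS(y, X).fit()
        k = X.shape[1] + 1  # + error variance
        logliks.append(float(fit.llf))
        bics.append(-2.0 * float(fit.llf) + k * math.log(n))
    return ModelComparison(
        candidates=[tuple(c) for c in candidate_predictor_sets],
        logliks=logliks,
        bics=bics,
        n_obs=n,
    )
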