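"""Association analysis of lesion morphology with atrial fibrillation.

The analysis pipeline on a cohort table:

* feature preparation — every continuous shape descriptor is natural-log
  transformed (they are strongly right-skewed) and z-scored; continuous
  clinical covariates (age, NIHSS) are z-scored without the log; binary
  indicators are left untouched. All logistic coefficients are therefore
  log-odds per SD (continuous) or per indicator (binary), which makes odds
  ratios comparable across variables.
* group comparisons — two-sided Mann-Whitney tests for continuous variables
  (median + IQR per group), chi-squared with a Monte-Carlo permutation
  p-value for frequencies (tables are resampled conditional on the margins;
  p = (1 + #{simulated chi2 >= observed}) / (1 + replicates)).
* univariate and multivariate logistic models with Wald 95% CIs; the default
  multivariate shape model excludes surface area, which is collinear with
  lesion volume.
* backward stepwise elimination at alpha = 0.05: refit, drop the least
  significant variable while its p exceeds alpha; ties broken by input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "SHAPE_FEATURES",
    "SHAPE_MODEL_VARS",
    "FULL_MODEL_VARS",
    "LogisticFit",
    "GroupComparison",
    "prepare_features",
    "fit_univariate",
    "fit_multivariate",
    "stepwise_eliminate",
    "compare_groups",
    "monte_carlo_chi2",
]

#: the six morphological descriptors (log + z-scored before modelling)
SHAPE_FEATURES = (
    "n_components",
    "volume_ml",
    "surface_area_mm2",
    "sphericity",
    "obb_volume_ml",
    "lesion_obb_ratio",
)

#: default multivariate shape model: surface area excluded (collinear with volume)
SHAPE_MODEL_VARS = (
    "n_components",
    "volume_ml",
    "sphericity",
    "obb_volume_ml",
    "lesion_obb_ratio",
)

#: shape + clinical + location model used for the stepwise refinement
FULL_MODEL_VARS = (
    "age",
    "sex",
    "nihss",
    "cortical_involved",
    "n_components",
    "multiple_territories",
    "volume_ml",
    "obb_volume_ml",
    "sphericity",
)

CLINICAL_CONTINUOUS = ("age", "nihss")

_Z = float(sps.norm.ppf(0.975))


@dataclass
class LogisticFit:
    """Per-variable odds ratios with Wald 95% CIs from a logistic model."""

    variables: list[str]
    coef: np.ndarray
    intercept: float
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    n: int
    converged: bool = True
    intercept_only: bool = False
    trace: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.variables,
            "coef": self.coef,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.pvalues,
            "n": self.n,
        })

    def p_of(self, variable: str) -> float:
        return float(self.pvalues[self.variables.index(variable)])


@dataclass
class GroupComparison:
    """Tidy per-variable group-difference table (medians/frequencies + p)."""

    table: pd.DataFrame
    group_sizes: tuple[int, int]


def prepare_features(
    cohort: pd.DataFrame,
    shape_features: tuple[str, ...] = SHAPE_FEATURES,
    clinical_continuous: tuple[str, ...] = CLINICAL_CONTINUOUS,
) -> pd.DataFrame:
    """Log + z-score shape features, z-score clinical covariates, in place of
    the raw columns (names unchanged). Binary columns pass through.

    Raises if a shape feature is non-positive (log undefined) or any scaled
    column has zero variance.
    """
    out = cohort.copy()
    for col in shape_features:
        if col not in out.columns:
            continue
        x = out[col].to_numpy(dtype=float)
        if np.any(x <= 0):
            raise ValueError(f"shape feature {col!r} has non-positive values; cannot log")
        out[col] = _zscore(np.log(x), col)
    for col in clinical_continuous:
        if col not in out.columns:
            continue
        out[col] = _zscore(out[col].to_numpy(dtype=float), col)
    return out


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"column {name!r} has zero variance; cannot z-score")
    return (x - x.mean()) / sd


def _design(cohort: pd.DataFrame, variables: list[str], outcome: str):
    cols = list(variables) + [outcome]
    data = cohort[cols].dropna()
    y = data[outcome].to_numpy(dtype=float)
    X = sm.add_constant(data[list(variables)].to_numpy(dtype=float), has_constant="add")
    return y, X, len(data)


def _fit_logit(y, X, variables: list[str], n: int, context: str) -> LogisticFit:
    if len(np.unique(y)) < 2:
        raise ValueError(f"{context}: outcome has a single class")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(f"{context}: logistic fit failed ({exc})") from exc
    fitted = res.predict(X)
    if np.all((fitted < 1e-8) | (fitted > 1 - 1e-8)):
        raise ValueError(f"{context}: logistic fit failed (complete separation)")
    params = res.params
    bse = res.bse
    coef = params[1:]
    lo = np.exp(coef - _Z * bse[1:])
    hi = np.exp(coef + _Z * bse[1:])
    return LogisticFit(
        variables=list(variables),
        coef=coef,
        intercept=float(params[0]),
        odds_ratio=np.exp(coef),
        ci_low=lo,
        ci_high=hi,
        pvalues=np.asarray(res.pvalues[1:]),
        n=n,
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def fit_univariate(cohort: pd.DataFrame, variable: str, outcome: str = "af") -> LogisticFit:
    """Maximum-likelihood logistic fit of the outcome on one prepared variable."""
    y, X, n = _design(cohort, [variable], outcome)
    try:
        return _fit_logit(y, X, [variable], n, f"univariate model for {variable!r}")
    except ValueError as exc:
        if "fit failed" in str(exc):
            raise ValueError(
                f"complete separation or singular fit for variable {variable!r}"
            ) from exc
        raise


def fit_multivariate(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] = SHAPE_MODEL_VARS,
    outcome: str = "af",
) -> LogisticFit:
    """Joint logistic fit; refuses rank-deficient designs, naming the
    collinear columns."""
    variables = list(variables)
    if "surface_area_mm2" in variables and variables == list(SHAPE_MODEL_VARS):
        raise AssertionError("default shape model must not contain surface area")
    y, X, n = _design(cohort, variables, outcome)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        suspects = _collinear_columns(X[:, 1:], variables)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {suspects}")
    return _fit_logit(y, X, variables, n, "multivariate model")


def _collinear_columns(X: np.ndarray, variables: list[str]) -> list[str]:
    _, r = np.linalg.qr(X - X.mean(axis=0))
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-10 if diag.size else 0.0
    return [v for v, d in zip(variables, diag) if d <= tol]


def stepwise_eliminate(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] = FULL_MODEL_VARS,
    alpha: float = 0.05,
    outcome: str = "af",
) -> LogisticFit:
    """Backward elimination: refit and drop the least significant variable
    while its p-value exceeds ``alpha``; ties broken by input order.

    The removal trace (variable, p at removal, remaining set) is attached to
    the returned fit. If every variable is eliminated the fit is flagged
    ``intercept_only``.
    """
    remaining = list(variables)
    trace: list[dict] = []
    step = 0
    while remaining:
        fit = fit_multivariate(cohort, tuple(remaining), outcome=outcome)
        worst_i = int(np.argmax(fit.pvalues))  # first occurrence wins ties
        worst_p = float(fit.pvalues[worst_i])
        if worst_p <= alpha:
            fit.trace = trace
            return fit
        step += 1
        removed = remaining.pop(worst_i)
        trace.append({
            "step": step,
            "removed": removed,
            "p": worst_p,
            "remaining": list(remaining),
        })
    # every variable eliminated: intercept-only model
    y = cohort[outcome].dropna().to_numpy(dtype=float)
    n = len(y)
    res = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
    empty = np.array([])
    return LogisticFit(
        variables=[], coef=empty, intercept=float(res.params[0]),
        odds_ratio=empty, ci_low=empty, ci_high=empty, pvalues=empty,
        n=n, intercept_only=True, trace=trace,
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _chi2_stat(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def _sample_margin_fixed(row_totals, col_totals, reps: int, rng) -> np.ndarray:
    """Sample r x c tables uniformly conditional on both margins."""
    r = len(row_totals)
    if r == 2:
        top = rng.multivariate_hypergeometric(col_totals, int(row_totals[0]), size=reps)
        bottom = np.asarray(col_totals)[None, :] - top
        return np.stack([top, bottom], axis=1)
    tables = np.empty((reps, r, len(col_totals)), dtype=np.int64)
    for t in range(reps):
        remaining = np.asarray(col_totals, dtype=np.int64).copy()
        for i in range(r - 1):
            row = rng.multivariate_hypergeometric(remaining, int(row_totals[i]))
            tables[t, i] = row
            remaining -= row
        tables[t, r - 1] = remaining
    return tables


def monte_carlo_chi2(
    table: np.ndarray,
    reps: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Chi-squared statistic and Monte-Carlo permutation p-value.

    Tables are resampled conditional on the observed margins (the permutation
    null); p = (1 + #{simulated >= observed}) / (1 + reps), so p is never 0
    and is reproducible under a fixed seed.
    """
    if seed is None:
        raise ValueError("monte_carlo_chi2 requires a seed for reproducibility")
    table = np.asarray(table, dtype=np.int64)
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    rng = np.random.default_rng(seed)
    observed = _chi2_stat(table)
    sims = _sample_margin_fixed(table.sum(axis=1), table.sum(axis=0), reps, rng)
    sim_stats = _chi2_vectorized(sims)
    p = (1.0 + float(np.sum(sim_stats >= observed - 1e-12))) / (1.0 + reps)
    return observed, p


def _chi2_vectorized(tables: np.ndarray) -> np.ndarray:
    tables = tables.astype(float)
    row = tables.sum(axis=2, keepdims=True)
    col = tables.sum(axis=1, keepdims=True)
    expected = row * col / tables.sum(axis=(1, 2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (tables - expected) ** 2 / expected, 0.0)
    return terms.sum(axis=(1, 2))


def compare_groups(
    cohort: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "nihss") + SHAPE_FEATURES,
    categorical: tuple[str, ...] = ("sex", "cortical_involved",
                                    "multiple_territories", "bilateral"),
    group_col: str = "af",
    mc_reps: int = 10000,
    seed: int | None = 0,
) -> GroupComparison:
    """Mann-Whitney (continuous) and Monte-Carlo chi-squared (categorical)
    group differences between the two outcome groups, on *raw* (unprepared)
    variables, reported as medians + IQR or counts + %."""
    groups = cohort[group_col].to_numpy()
    g0, g1 = cohort[groups == 0], cohort[groups == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both outcome groups must be non-empty")
    rows = []
    for var in continuous:
        if var not in cohort.columns:
            continue
        x0 = g0[var].dropna().to_numpy(dtype=float)
        x1 = g1[var].dropna().to_numpy(dtype=float)
        u, p = sps.mannwhitneyu(x0, x1, alternative="two-sided")
        rows.append({
            "variable": var, "type": "continuous", "test": "mann-whitney",
            "stat": float(u), "p": float(p),
            "group0_median": float(np.median(x0)),
            "group0_q1": float(np.percentile(x0, 25)),
            "group0_q3": float(np.percentile(x0, 75)),
            "group1_median": float(np.median(x1)),
            "group1_q1": float(np.percentile(x1, 25)),
            "group1_q3": float(np.percentile(x1, 75)),
        })
    for i, var in enumerate(categorical):
        if var not in cohort.columns:
            continue
        tab = pd.crosstab(cohort[group_col], cohort[var].astype(int)).to_numpy()
        if tab.shape[1] < 2:  # constant variable: no test possible
            stat, p = np.nan, np.nan
        else:
            stat, p = monte_carlo_chi2(tab, reps=mc_reps,
                                       seed=None if seed is None else seed + i)
        n0_pos = int((g0[var].astype(float) > 0).sum())
        n1_pos = int((g1[var].astype(float) > 0).sum())
        rows.append({
            "variable": var, "type": "categorical", "test": "chi2-monte-carlo",
            "stat": stat, "p": p,
            "group0_count": n0_pos, "group0_pct": 100.0 * n0_pos / len(g0),
            "group1_count": n1_pos, "group1_pct": 100.0 * n1_pos / len(g1),
        })
    return GroupComparison(table=pd.DataFrame(rows), group_sizes=(len(g0), len(g1)))
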