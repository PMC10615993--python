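"""Validation statistics: correlations with CIs, correlation-difference tests,
rater agreement, single-factor reliability, incremental-validity regression,
and group comparisons.

Conventions
-----------
* Correlation CIs use the Fisher z transform with SE ``1/sqrt(n - 3)``.
* The dependent-correlation test is the overlapping-variable Fisher-z form
  with the back-transformed mean correlation (Steiger's Z1*); its difference
  CI uses Zou's (2007) method.
* The independent-correlation test is the classic two-sample Fisher z test.
* Cohen's d uses the pooled SD; its CI uses the large-sample normal
  approximation of the d sampling variance (documented, slightly narrower
  than the noncentral-t interval).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InvalidInputError, InvalidParameterError, UndefinedStatisticError

__all__ = [
    "CorrelationResult",
    "CorrelationComparison",
    "GroupComparison",
    "RegressionStep",
    "RegressionResult",
    "pearson_ci",
    "fisher_ci",
    "compare_dependent_correlations",
    "compare_independent_correlations",
    "single_rater_average",
    "omega_single_factor",
    "icc",
    "hierarchical_regression",
    "group_comparison",
    "cohens_d_from_stats",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    level: float = 0.95


def fisher_ci(r: float, n: int, level: float = 0.95) -> CorrelationResult:
    """Fisher-z confidence interval for a correlation given r and n."""
    if n < 4:
        raise InvalidInputError("Fisher CI requires n >= 4")
    if not -1.0 <= r <= 1.0:
        raise InvalidParameterError("correlation outside [-1, 1]")
    if abs(r) == 1.0:
        return CorrelationResult(r, r, r, n, level)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    return CorrelationResult(
        r, float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)), n, level
    )


def pearson_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Pearson r between two samples with its Fisher-z CI."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D arrays of equal length")
    if x.size < 4:
        raise InvalidInputError("pearson_ci requires n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("non-finite values in input")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedStatisticError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) >= 1.0 - 1e-12:  # numerically perfect correlation -> degenerate CI
        r = float(np.sign(r))
    return fisher_ci(r, x.size, level)


@dataclass(frozen=True)
class CorrelationComparison:
    diff: float
    z: float
    p: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def compare_dependent_correlations(
    r1y: float, r2y: float, r12: float, n: int, level: float = 0.95
) -> CorrelationComparison:
    """Test of two overlapping dependent correlations sharing variable y.

    Statistic (Steiger's Z1*, Fisher-z form with back-transformed mean r):

        rbar = tanh((atanh(r1y) + atanh(r2y)) / 2)
        f    = (1 - r12) / (2 (1 - rbar^2))        (capped at 1)
        h    = (1 - f rbar^2) / (1 - rbar^2)
        z    = (atanh(r1y) - atanh(r2y)) * sqrt((n - 3) / (2 (1 - r12) h))

    The difference CI uses Zou's (2007) method.
    """
    for name, r in (("r1y", r1y), ("r2y", r2y), ("r12", r12)):
        if not -1.0 < r < 1.0:
            raise InvalidParameterError(f"{name} must be in (-1, 1)")
    if n < 10:
        raise InvalidInputError("compare_dependent_correlations requires n >= 10")
    det = 1.0 + 2.0 * r1y * r2y * r12 - r1y**2 - r2y**2 - r12**2
    if det <= 0:
        raise InvalidInputError("correlation matrix is not positive definite")
    z1, z2 = np.arctanh(r1y), np.arctanh(r2y)
    rbar = float(np.tanh((z1 + z2) / 2.0))
    f = min((1.0 - r12) / (2.0 * (1.0 - rbar**2)), 1.0)
    h = (1.0 - f * rbar**2) / (1.0 - rbar**2)
    z = float((z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    lo, hi = _zou_dependent_ci(r1y, r2y, r12, n, level)
    return CorrelationComparison(diff=r1y - r2y, z=z, p=p, ci_low=lo, ci_high=hi)


def _zou_dependent_ci(r1: float, r2: float, r12: float, n: int, level: float):
    c = (
        (r12 - 0.5 * r1 * r2) * (1 - r1**2 - r2**2 - r12**2) + r12**3
    ) / ((1 - r1**2) * (1 - r2**2))
    ci1 = fisher_ci(r1, n, level)
    ci2 = fisher_ci(r2, n, level)
    l1, u1 = ci1.ci_low, ci1.ci_high
    l2, u2 = ci2.ci_low, ci2.ci_high
    lo = r1 - r2 - np.sqrt((r1 - l1) ** 2 + (u2 - r2) ** 2 - 2 * c * (r1 - l1) * (u2 - r2))
    hi = r1 - r2 + np.sqrt((u1 - r1) ** 2 + (r2 - l2) ** 2 - 2 * c * (u1 - r1) * (r2 - l2))
    return float(lo), float(hi)


def compare_independent_correlations(
    rA: float, nA: int, rB: float, nB: int
) -> CorrelationComparison:
    """Two-sample Fisher z test: z = (atanh(rA) - atanh(rB)) / sqrt(1/(nA-3) + 1/(nB-3))."""
    for name, r in (("rA", rA), ("rB", rB)):
        if not -1.0 < r < 1.0:
            raise InvalidParameterError(f"{name} must be in (-1, 1)")
    if nA < 4 or nB < 4:
        raise InvalidInputError("both samples need n >= 4")
    se = np.sqrt(1.0 / (nA - 3) + 1.0 / (nB - 3))
    z = float((np.arctanh(rA) - np.arctanh(rB)) / se)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CorrelationComparison(diff=rA - rB, z=z, p=p)


# ---------------------------------------------------------------------------
# rater statistics
# ---------------------------------------------------------------------------

def single_rater_average(ratings: pd.DataFrame, leave_one_out: bool = False) -> float:
    """Mean correlation of each rater with the across-rater mean rating.

    By default each rater is included in the mean they are correlated with
    (the literal composite); ``leave_one_out=True`` correlates each rater
    with the mean of the *other* raters instead. Raters with zero variance
    are excluded with a warning.
    """
    mat = ratings.to_numpy(dtype=np.float64)
    if mat.shape[1] < 2:
        raise InvalidInputError("single_rater_average requires >= 2 raters")
    mask = np.all(np.isfinite(mat), axis=1)
    mat = mat[mask]
    if mat.shape[0] < 4:
        raise InvalidInputError("too few complete stories")
    mean_all = mat.mean(axis=1)
    rs = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        if np.std(col) == 0.0:
            warnings.warn(f"rater column {j} has zero variance; excluded from sr_ave")
            continue
        target = (mean_all * mat.shape[1] - col) / (mat.shape[1] - 1) if leave_one_out else mean_all
        if np.std(target) == 0.0:
            warnings.warn(f"rater column {j}: comparison mean has zero variance; excluded")
            continue
        rs.append(float(np.corrcoef(col, target)[0, 1]))
    if not rs:
        raise UndefinedStatisticError("no rater with nonzero variance")
    return float(np.mean(rs))


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def _fit_one_factor(R: np.ndarray, tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """ML one-factor model on a correlation matrix: Sigma = lam lam' + diag(psi)."""
    k = R.shape[0]
    eigvals, eigvecs = np.linalg.eigh(R)
    lead = eigvecs[:, -1] * np.sqrt(max(eigvals[-1], 1e-6))
    if lead.sum() < 0:
        lead = -lead
    lam0 = np.clip(lead, -0.99, 0.99)
    psi0 = np.clip(1.0 - lam0**2, 1e-4, None)
    x0 = np.concatenate([lam0, np.log(psi0)])

    def objective(x):
        lam = x[:k]
        psi = np.exp(x[k:])
        Sigma = np.outer(lam, lam) + np.diag(psi)
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return 1e10
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        inv = np.linalg.inv(Sigma)
        return logdet + float(np.trace(R @ inv))

    res = optimize.minimize(objective, x0, method="L-BFGS-B", options={"maxiter": 2000, "ftol": tol})
    if not res.success and res.fun >= 1e9:
        raise UndefinedStatisticError(f"one-factor ML fit failed: {res.message}")
    lam = res.x[:k]
    psi = np.exp(res.x[k:])
    if lam.sum() < 0:
        lam = -lam
    return lam, psi


def omega_single_factor(indicators: pd.DataFrame | np.ndarray) -> float:
    """McDonald's omega from a one-factor ML model on the correlation matrix.

    omega = (sum lambda)^2 / ((sum lambda)^2 + sum theta) with standardized
    loadings lambda and unique variances theta. Heywood cases (theta <= 0
    at the boundary) are floored with a warning.
    """
    X = np.asarray(indicators, dtype=np.float64)
    n, k = X.shape
    if k < 3:
        raise InvalidInputError("omega requires k >= 3 indicators")
    if n <= k:
        raise InvalidInputError("omega requires more observations than indicators")
    mask = np.all(np.isfinite(X), axis=1)
    X = X[mask]
    R = np.corrcoef(X, rowvar=False)
    lam, psi = _fit_one_factor(R)
    if np.any(psi < 1e-3):
        warnings.warn("Heywood case: unique variance at boundary, floored at 0")
        psi = np.clip(psi, 0.0, None)
    s = lam.sum()
    return float(s**2 / (s**2 + psi.sum()))


@dataclass(frozen=True)
class ICCResult:
    single: float  # ICC(2,1): two-way random, absolute agreement, single rater
    average: float  # ICC(2,k)
    n_stories: int
    n_raters: int


def icc(ratings: pd.DataFrame) -> ICCResult:
    """Two-way random-effects absolute-agreement ICCs from the mean-squares decomposition.

    Incomplete stories are listwise-deleted (logged).
    """
    mat = ratings.to_numpy(dtype=np.float64)
    complete = np.all(np.isfinite(mat), axis=1)
    if not np.all(complete):
        logger.info("icc: dropping %d incomplete stories", int((~complete).sum()))
    mat = mat[complete]
    n, k = mat.shape
    if n < 2 or k < 2:
        raise InvalidInputError("icc requires >= 2 stories and >= 2 raters")
    grand = mat.mean()
    row_means = mat.mean(axis=1)
    col_means = mat.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((mat - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    average = (msr - mse) / (msr + (msc - mse) / n)
    return ICCResult(float(single), float(average), n, k)


# ---------------------------------------------------------------------------
# incremental-validity regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionStep:
    coefficients: pd.DataFrame  # index: term; columns: b, b_ci_low, b_ci_high, b_std, b_std_ci_low, b_std_ci_high, p
    r2: float
    r2_ci: tuple[float, float] = (float("nan"), float("nan"))


@dataclass
class RegressionResult:
    step1: RegressionStep
    step2: RegressionStep
    delta_r2: float
    delta_r2_ci: tuple[float, float] = field(default=(float("nan"), float("nan")))
    n: int = 0


def _ols(y: np.ndarray, X: pd.DataFrame, level: float = 0.95) -> tuple[pd.DataFrame, float]:
    import statsmodels.api as sm

    design = sm.add_constant(X)
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=1.0 - level)
    coef = pd.DataFrame(
        {
            "b": fit.params,
            "b_ci_low": ci[0],
            "b_ci_high": ci[1],
            "p": fit.pvalues,
        }
    )
    return coef, float(fit.rsquared)


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    return (a - a.mean(axis=0)) / sd


def hierarchical_regression(
    y,
    step1: pd.DataFrame,
    step2: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> RegressionResult:
    """Two-step OLS with standardized coefficients and a bootstrap ΔR² CI.

    Step 1 regresses y on the ``step1`` predictors; step 2 adds the
    ``step2`` predictors. Standardized weights come from refitting on
    z-scored variables. The ΔR² (and R²) CIs are percentile bootstrap over
    complete-case rows (``n_boot`` resamples, seeded).
    """
    y = np.asarray(y, dtype=np.float64)
    X1 = step1.astype(np.float64)
    X2 = step2.astype(np.float64)
    if len(set(X1.columns) & set(X2.columns)) > 0:
        raise InvalidParameterError("step1 and step2 predictors must be disjoint")
    X_full = pd.concat([X1, X2], axis=1)
    keep = np.isfinite(y) & np.all(np.isfinite(X_full.to_numpy()), axis=1)
    y, X1, X2 = y[keep], X1.loc[keep], X2.loc[keep]
    X_full = X_full.loc[keep]
    n = y.size
    if n <= X_full.shape[1] + 1:
        raise InvalidInputError("too few complete cases for the full model")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X_full.to_numpy()]))
    if rank < X_full.shape[1] + 1:
        corr = X_full.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise InvalidInputError(f"perfect collinearity among predictors (check {worst})")

    def fit_step(Xs: pd.DataFrame) -> RegressionStep:
        coef, r2 = _ols(y, Xs, level)
        zy = _zscore(y)
        zX = pd.DataFrame(_zscore(Xs.to_numpy()), columns=Xs.columns, index=Xs.index)
        zcoef, _ = _ols(zy, zX, level)
        coef["b_std"] = zcoef["b"]
        coef["b_std_ci_low"] = zcoef["b_ci_low"]
        coef["b_std_ci_high"] = zcoef["b_ci_high"]
        return RegressionStep(coefficients=coef, r2=r2)

    s1 = fit_step(X1)
    s2 = fit_step(X_full)
    delta = s2.r2 - s1.r2

    rng = np.random.default_rng(seed)
    r2_1 = np.empty(n_boot)
    r2_2 = np.empty(n_boot)
    A1 = np.column_stack([np.ones(n), X1.to_numpy()])
    A2 = np.column_stack([np.ones(n), X_full.to_numpy()])
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        tss = np.sum((yb - yb.mean()) ** 2)
        if tss == 0:
            r2_1[b] = r2_2[b] = np.nan
            continue
        for arr, A in ((r2_1, A1[idx]), (r2_2, A2[idx])):
            beta, _, _, _ = np.linalg.lstsq(A, yb, rcond=None)
            resid = yb - A @ beta
            arr[b] = 1.0 - np.sum(resid**2) / tss
    deltas = r2_2 - r2_1
    alpha = 1.0 - level
    s1.r2_ci = tuple(np.nanpercentile(r2_1, [100 * alpha / 2, 100 * (1 - alpha / 2)]))
    s2.r2_ci = tuple(np.nanpercentile(r2_2, [100 * alpha / 2, 100 * (1 - alpha / 2)]))
    d_ci = tuple(np.nanpercentile(deltas, [100 * alpha / 2, 100 * (1 - alpha / 2)]))
    return RegressionResult(step1=s1, step2=s2, delta_r2=delta, delta_r2_ci=d_ci, n=n)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    t: float
    df: float
    p: float
    d: float
    d_ci_low: float
    d_ci_high: float


def cohens_d_from_stats(
    mA: float, sdA: float, nA: int, mB: float, sdB: float, nB: int, level: float = 0.95
) -> GroupComparison:
    """Welch t and pooled-SD Cohen's d from summary statistics.

    The d CI uses the normal approximation with
    Var(d) = (nA+nB)/(nA nB) + d^2 / (2 (nA+nB-2)).
    """
    if nA < 2 or nB < 2:
        raise InvalidInputError("both groups need n >= 2")
    vA, vB = sdA**2, sdB**2
    if vA == 0.0 and vB == 0.0:
        raise UndefinedStatisticError("zero variance in both groups")
    se2 = vA / nA + vB / nB
    t = (mA - mB) / np.sqrt(se2)
    df = se2**2 / ((vA / nA) ** 2 / (nA - 1) + (vB / nB) ** 2 / (nB - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    sp = np.sqrt(((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2))
    d = float((mA - mB) / sp)
    var_d = (nA + nB) / (nA * nB) + d**2 / (2.0 * (nA + nB - 2))
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    half = zcrit * np.sqrt(var_d)
    return GroupComparison(float(t), float(df), p, d, d - half, d + half)


def group_comparison(xA, xB, level: float = 0.95) -> GroupComparison:
    """Welch's t with Satterthwaite df and pooled-SD Cohen's d from raw samples."""
    xA = np.asarray(xA, dtype=np.float64)
    xB = np.asarray(xB, dtype=np.float64)
    xA = xA[np.isfinite(xA)]
    xB = xB[np.isfinite(xB)]
    return cohens_d_from_stats(
        float(xA.mean()), float(xA.std(ddof=1)), xA.size,
        float(xB.mean()), float(xB.std(ddof=1)), xB.size,
        level=level,
    )
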