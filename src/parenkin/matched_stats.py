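"""Matched case-control inference for breast-wise kinetic measures.

Implements the statistical toolkit of a 1:1 matched case-control study:

* conditional logistic regression (CLR) on within-pair differences — the
  conditional likelihood of a 1:1 matched design reduces to
  ``L(beta) = prod_i sigma(beta' d_i)`` with ``d_i`` the case-minus-control
  covariate difference of pair i, i.e. logistic regression without
  intercept on the pair differences with outcome identically 1;
* unconditional logistic regression (via statsmodels) with ROC/AUC, the AUC
  computed as the tie-corrected Mann-Whitney statistic with a DeLong
  confidence interval;
* leave-one-out cross-validated AUC (one ROC over all held-out predicted
  probabilities);
* likelihood-ratio tests between nested logistic models;
* Spearman rank correlation.

Odds ratios are reported per a declared unit for each covariate (e.g. per
0.01 wash-in slope variance, per 100 cm^3 SER volume, per 20 percentage
points of BPE%): OR = exp(beta * unit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, log_expit
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import MatchedCohort

__all__ = [
    "CLRFit",
    "LogisticFit",
    "ROCResult",
    "LRTResult",
    "clr_fit",
    "clr_fit_diffs",
    "logistic_fit",
    "auc",
    "loocv_auc",
    "lrt",
    "spearman",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class CLRFit:
    """Conditional logistic regression fit on 1:1 matched pairs."""

    covariates: list[str]
    units: np.ndarray
    coef: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_pairs: int
    message: str = ""

    @property
    def odds_ratios(self) -> np.ndarray:
        """OR per declared unit: exp(coef * unit)."""
        with np.errstate(over="ignore"):
            return np.exp(self.coef * self.units)

    @property
    def or_ci_low(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.ci_low * self.units)

    @property
    def or_ci_high(self) -> np.ndarray:
        # infinite upper bound signals a degenerate (separated) fit
        with np.errstate(over="ignore"):
            return np.exp(self.ci_high * self.units)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "unit": self.units,
                "coef": self.coef,
                "se": self.se,
                "or": self.odds_ratios,
                "or_ci_low": self.or_ci_low,
                "or_ci_high": self.or_ci_high,
                "p_value": self.p_values,
            }
        )


@dataclass
class LogisticFit:
    """Unconditional logistic regression fit (intercept included)."""

    covariates: list[str]
    params: np.ndarray  # intercept first
    se: np.ndarray
    loglik: float
    fitted: np.ndarray
    labels: np.ndarray
    converged: bool
    n: int
    message: str = ""

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.covariates].to_numpy(dtype=float)
        return expit(self.params[0] + x @ self.params[1:])


@dataclass
class ROCResult:
    """AUC with DeLong 95% CI and the ROC curve points."""

    auc: float
    ci_low: float
    ci_high: float
    se: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    n_flagged_folds: int = 0


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# conditional logistic regression
# ---------------------------------------------------------------------------


def _clr_loglik(beta: np.ndarray, d: np.ndarray) -> float:
    return float(np.sum(log_expit(d @ beta)))


def clr_fit_diffs(
    diffs: np.ndarray,
    covariates: Sequence[str] | None = None,
    units: Sequence[float] | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CLRFit:
    """Fit the 1:1 conditional logistic likelihood on pair differences.

    Newton-Raphson from beta = 0 with analytic gradient and Hessian and
    step-halving on likelihood decrease; convergence when the largest score
    component falls below ``tol``.  Wald standard errors come from the
    inverse observed information.

    A covariate whose differences are all zero is non-identifiable and
    raises ``ValueError``.  Complete separation (some direction along which
    every difference is strictly positive) sends the MLE to infinity; the
    fit is then flagged ``converged=False`` with a diagnostic message and no
    silent estimate should be trusted.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    n, p = d.shape
    if n < 1:
        raise ValueError("need at least one pair")
    if covariates is None:
        covariates = [f"x{j}" for j in range(p)]
    covariates = list(covariates)
    if units is None:
        units = np.ones(p)
    units = np.asarray(units, dtype=float)

    zero_cols = [covariates[j] for j in range(p) if np.all(d[:, j] == 0.0)]
    if zero_cols:
        raise ValueError(
            "non-identifiable: all within-pair differences are zero for "
            + ", ".join(zero_cols)
        )

    beta = np.zeros(p)
    ll = _clr_loglik(beta, d)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        prob = expit(d @ beta)
        score = d.T @ (1.0 - prob)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = prob * (1.0 - prob)
        info = (d * w[:, None]).T @ d  # observed information (negative Hessian)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step-halving keeps the likelihood non-decreasing
        for _ in range(40):
            cand = beta + step
            ll_new = _clr_loglik(cand, d)
            if ll_new >= ll:
                break
            step = 0.5 * step
        beta = beta + step
        ll = _clr_loglik(beta, d)

    # separation diagnostic: when some direction makes every difference
    # strictly one-signed, the conditional MLE diverges and the fitted
    # probability of each discordant pair tends to 1
    nonzero = np.any(d != 0.0, axis=1)
    if converged and nonzero.any():
        if float(np.min(expit(d[nonzero] @ beta))) > 1.0 - 1e-4:
            converged = False
    if not converged and not message:
        message = (
            "non-convergence: possible complete separation "
            "(conditional MLE diverging)"
        )

    prob = expit(d @ beta)
    w = prob * (1.0 - prob)
    info = (d * w[:, None]).T @ d
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return CLRFit(
        covariates=covariates,
        units=units,
        coef=beta,
        se=se,
        ci_low=beta - _Z975 * se,
        ci_high=beta + _Z975 * se,
        p_values=pvals,
        loglik=ll,
        converged=converged,
        n_iter=it,
        n_pairs=n,
        message=message,
    )


def clr_fit(
    cohort: MatchedCohort,
    covariates: Sequence[str],
    units: dict[str, float] | None = None,
) -> CLRFit:
    """Conditional logistic regression of case status on cohort covariates.

    ``units`` maps covariate names to the per-unit OR scale (default 1).
    """
    covariates = list(covariates)
    d = cohort.diff_matrix(covariates)
    u = np.array([1.0 if units is None else units.get(c, 1.0) for c in covariates])
    return clr_fit_diffs(d, covariates=covariates, units=u)


# ---------------------------------------------------------------------------
# unconditional logistic regression, ROC / AUC, LOOCV, LRT
# ---------------------------------------------------------------------------


def logistic_fit(
    table: pd.DataFrame,
    covariates: Sequence[str],
    label_col: str = "is_case",
) -> LogisticFit:
    """Maximum-likelihood logistic regression with intercept.

    ``covariates`` may be empty (intercept-only model).  Perfect separation
    is flagged (``converged=False``) rather than raised.
    """
    covariates = list(covariates)
    y = table[label_col].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    x = table[covariates].to_numpy(dtype=float) if covariates else np.empty((len(y), 0))
    design = np.column_stack([np.ones(len(y)), x])

    model = sm.Logit(y, design)
    converged = True
    message = ""
    try:
        res = model.fit(disp=0, method="newton", maxiter=100)
        converged = bool(res.mle_retvals.get("converged", True))
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        res = model.fit(disp=0, method="lbfgs", maxiter=500)
        converged = False
        message = f"separation or singular fit: {exc}"
    params = np.asarray(res.params, dtype=float)
    if np.max(np.abs(params)) > 50.0:
        converged = False
        message = message or "extreme coefficients: possible separation"
    with np.errstate(invalid="ignore"):
        se = np.asarray(res.bse, dtype=float)
    return LogisticFit(
        covariates=covariates,
        params=params,
        se=se,
        loglik=float(res.llf),
        fitted=np.asarray(res.predict(design), dtype=float),
        labels=y.astype(int),
        converged=converged,
        n=len(y),
        message=message,
    )


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC (ties count one half)."""
    ranks = stats.rankdata(scores)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    rank_sum = float(np.sum(ranks[labels == 1]))
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _delong_se(scores: np.ndarray, labels: np.ndarray, a: float) -> float:
    """DeLong standard error of the AUC via structural components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)  # per-positive components
    v01 = psi.mean(axis=0)  # per-negative components
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC analysis of scores against binary labels.

    AUC is the tie-corrected Mann-Whitney statistic; its 95% CI uses
    DeLong's variance estimate (clipped to [0, 1]); curve points come from a
    threshold sweep.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")

    a = _mann_whitney_auc(scores, labels)
    se = _delong_se(scores, labels, a)
    fpr, tpr, thresh = roc_curve(labels, scores)
    return ROCResult(
        auc=a,
        ci_low=float(max(0.0, a - _Z975 * se)),
        ci_high=float(min(1.0, a + _Z975 * se)),
        se=se,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresh,
        scores=scores,
        labels=labels,
    )


def loocv_auc(
    table: pd.DataFrame,
    covariates: Sequence[str],
    label_col: str = "is_case",
) -> ROCResult:
    """Leave-one-out cross-validated AUC.

    Each subject is scored by a logistic model refit on the remaining n-1
    subjects; all held-out probabilities are pooled into a single ROC.
    Folds with separation are flagged (count reported on the result) but
    still scored through the same fit.
    """
    n = len(table)
    if n < 10:
        raise ValueError("LOOCV requires n >= 10")
    table = table.reset_index(drop=True)
    held_out = np.empty(n)
    flagged = 0
    for i in range(n):
        train = table.drop(index=i)
        fit = logistic_fit(train, covariates, label_col=label_col)
        if not fit.converged:
            flagged += 1
        held_out[i] = fit.predict(table.iloc[[i]])[0]
    result = auc(held_out, table[label_col].to_numpy(dtype=int))
    result.n_flagged_folds = flagged
    return result


def lrt(nested_fit: LogisticFit, full_fit: LogisticFit) -> LRTResult:
    """Likelihood-ratio test between nested logistic models.

    The statistic is 2(l_full - l_nested) with df the parameter-count
    difference; models must be fitted on the same records and the nested
    covariate set must be a strict subset of the full one.
    """
    nested = set(nested_fit.covariates)
    full = set(full_fit.covariates)
    if not nested < full:
        raise ValueError("models are not nested (covariate sets)")
    if nested_fit.n != full_fit.n:
        raise ValueError("models must be fitted on identical records")
    df = len(full) - len(nested)
    statistic = 2.0 * (full_fit.loglik - nested_fit.loglik)
    p = float(stats.chi2.sf(statistic, df))
    return LRTResult(statistic=float(statistic), df=df, p_value=p)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p (t approximation).

    Average ranks are used for ties.  Requires n >= 4 and non-constant
    inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
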