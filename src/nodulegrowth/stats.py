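"""Cohort statistics: group summaries, two-group tests, contingency analysis,
logistic regression, and ROC analysis with threshold selection.

Standard tests are delegated to scipy/statsmodels.  The ROC machinery is
implemented here directly: the AUC through the rank (Mann-Whitney)
construction with midrank tie handling, its 95% confidence interval by
DeLong's covariance estimator, and the operating threshold by maximising
Youden's J = sensitivity + specificity - 1 over the observed cut-points.
For doubling times the clinically relevant direction is lower-is-positive
(shorter doubling time means faster growth, hence higher metastasis risk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "DegenerateTableError",
    "InsufficientDataError",
    "RocSummary",
    "LogisticFit",
    "percent_half_up",
    "format_p",
    "summarize_groups",
    "compare_continuous",
    "compare_categorical",
    "contingency_coefficient",
    "univariable_screen",
    "fit_logistic",
    "roc_auc",
    "youden_threshold",
    "roc_analysis",
]


class DegenerateTableError(ValueError):
    """Contingency table with an all-zero row or column (or empty)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested comparison."""


class UndefinedAUCError(ValueError):
    """ROC requested with only one outcome class present."""


# --------------------------------------------------------------------------
# presentation helpers


def percent_half_up(count: float, total: float, decimals: int = 1) -> float:
    """Percentage with half-up rounding at ``decimals`` places (the rounding
    convention of clinical tables, unlike banker's rounding)."""
    if total == 0:
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(str(count)) * 100 / Decimal(str(total))).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


def format_p(p: float) -> str:
    """p-value to three decimals with '<0.001' flooring."""
    if math.isnan(p):
        return "NA"
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


# --------------------------------------------------------------------------
# group summaries and two-group tests


def summarize_groups(
    df: pd.DataFrame,
    group: str,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-group summary table: continuous variables as mean +/- SD,
    categorical as count (percent).

    One row per (variable, level); percent columns use one-decimal half-up
    rounding.  Empty groups yield zero counts rather than an error.
    """
    levels = list(pd.unique(df[group].dropna()))
    rows = []
    for var in continuous:
        row = {"variable": var, "level": "mean_sd"}
        for lv in levels:
            x = pd.to_numeric(df.loc[df[group] == lv, var], errors="coerce").dropna()
            mean = x.mean() if len(x) else float("nan")
            sd = x.std(ddof=1) if len(x) > 1 else 0.0
            row[f"{lv}"] = f"{mean:.2f} ± {sd:.2f}"
        rows.append(row)
    for var in categorical:
        var_levels = list(pd.unique(df[var].dropna()))
        totals = {lv: int((df[group] == lv).sum()) for lv in levels}
        for vl in var_levels:
            row = {"variable": var, "level": str(vl)}
            for lv in levels:
                n = int(((df[group] == lv) & (df[var] == vl)).sum())
                row[f"{lv}"] = f"{n}({percent_half_up(n, totals[lv])})" if totals[lv] else f"{n}(0)"
            rows.append(row)
    return pd.DataFrame(rows)


def compare_continuous(
    x: Sequence[float], y: Sequence[float], method: str = "welch_t"
) -> dict:
    """Two-sided two-group comparison of a continuous variable.

    ``welch_t`` is the unequal-variance t-test; ``mann_whitney`` is the
    asymptotic rank-sum test with tie correction.  Returns the p-value, the
    test statistic, the mean difference, and the method used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    effect = float(np.mean(x) - np.mean(y))
    if method == "welch_t":
        res = sps.ttest_ind(x, y, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "mann_whitney":
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            # all observations tied: no evidence of any difference
            stat, p = float(len(x) * len(y) / 2.0), 1.0
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"p": p, "statistic": stat, "effect": effect, "method": method}


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.size == 0 or t.sum() <= 0:
        raise DegenerateTableError("need a non-empty 2-D table of counts")
    if np.any(t < 0):
        raise DegenerateTableError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateTableError("table has an all-zero row or column")
    return t


def compare_categorical(table, correction: bool = False) -> dict:
    """Pearson chi-square test on a contingency table.

    No continuity correction by default (matching common statistical-package
    defaults for tables larger than 2x2); set ``correction=True`` for the
    Yates-corrected 2x2 test.
    """
    t = _as_table(table)
    chi2, p, dof, expected = sps.chi2_contingency(t, correction=correction)
    return {"chi2": float(chi2), "df": int(dof), "p": float(p), "expected": expected}


def contingency_coefficient(table) -> float:
    """Pearson contingency coefficient C = sqrt(chi2 / (chi2 + n)) in [0, 1)."""
    t = _as_table(table)
    chi2 = compare_categorical(t)["chi2"]
    return math.sqrt(chi2 / (chi2 + t.sum()))


def univariable_screen(
    df: pd.DataFrame,
    outcome: str,
    variables: Sequence[str],
    continuous_method: str = "welch_t",
) -> pd.DataFrame:
    """Variable-by-variable association screen against a binary outcome.

    Continuous variables are compared between outcome groups
    (:func:`compare_continuous`); categorical variables by chi-square on the
    cross-tabulation.  Constant variables are flagged with an undefined p.
    The report preserves the order of ``variables``.
    """
    y = df[outcome]
    levels = pd.unique(y.dropna())
    if len(levels) != 2:
        raise ValueError(f"outcome {outcome!r} must be binary, got {list(levels)}")
    rows = []
    for var in variables:
        col = df[var]
        numeric = pd.api.types.is_numeric_dtype(col) and col.nunique() > 2
        if col.dropna().nunique() <= 1:
            rows.append(
                {"variable": var, "kind": "constant", "p": float("nan"),
                 "p_formatted": "NA", "flag": "constant"}
            )
            continue
        if numeric:
            g0 = col[y == levels[0]].dropna()
            g1 = col[y == levels[1]].dropna()
            res = compare_continuous(g0, g1, method=continuous_method)
            rows.append(
                {"variable": var, "kind": "continuous", "p": res["p"],
                 "p_formatted": format_p(res["p"]), "flag": ""}
            )
        else:
            tab = pd.crosstab(col, y).to_numpy()
            flag = ""
            try:
                res = compare_categorical(tab)
                p = res["p"]
            except DegenerateTableError:
                p, flag = float("nan"), "degenerate"
            if p == 0.0:
                flag = "separated"
            rows.append(
                {"variable": var, "kind": "categorical", "p": p,
                 "p_formatted": format_p(p) if flag != "degenerate" else "NA",
                 "flag": flag}
            )
    return pd.DataFrame(rows, columns=["variable", "kind", "p", "p_formatted", "flag"])


# --------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit: per-variable odds ratios with Wald
    95% CIs and p-values, plus convergence/separation diagnostics."""

    table: pd.DataFrame  # columns: variable, or_, ci_low, ci_high, p
    converged: bool
    log_likelihood: float
    separation: bool = False
    n_obs: int = 0

    @property
    def reliable(self) -> bool:
        return self.converged and not self.separation

    def summary(self) -> pd.DataFrame:
        out = self.table.copy()
        out["p_formatted"] = out["p"].map(format_p)
        return out


def fit_logistic(
    df: pd.DataFrame, outcome: str, covariates: Sequence[str]
) -> LogisticFit:
    """Binomial logistic regression of a 0/1 outcome on covariates.

    Odds ratios are exponentiated coefficients with Wald 95% confidence
    intervals.  Complete or quasi-complete separation and non-convergence are
    detected and flagged on the result rather than raised, so a screening
    loop can keep going; ``reliable`` is False for such fits.  With zero
    covariates an intercept-only model is fitted (fitted probability equals
    the outcome prevalence).
    """
    y = np.asarray(df[outcome], dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    X = df[list(covariates)].astype(float) if covariates else pd.DataFrame(index=df.index)
    if len(df) <= len(covariates):
        raise InsufficientDataError("need n > number of covariates")
    X = sm.add_constant(X, has_constant="add")
    separation = False
    converged = False
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        fitted = res.predict(X)
        # fitted probabilities pinned to 0/1 indicate (quasi-)separation
        separation = bool(np.any((fitted > 1 - 1e-8) | (fitted < 1e-8)))
        params, bse, pvals, llf = res.params, res.bse, res.pvalues, float(res.llf)
    except Exception:  # PerfectSeparationError and numerical failures
        separation = True
        k = X.shape[1]
        params = pd.Series(np.full(k, np.nan), index=X.columns)
        bse = pd.Series(np.full(k, np.nan), index=X.columns)
        pvals = pd.Series(np.full(k, np.nan), index=X.columns)
        llf = float("nan")
    z = sps.norm.ppf(0.975)
    rows = []
    for name in X.columns:
        if name == "const":
            continue
        b, se = float(params[name]), float(bse[name])
        with np.errstate(over="ignore"):
            rows.append(
                {
                    "variable": name,
                    "or_": float(np.exp(b)),
                    "ci_low": float(np.exp(b - z * se)),
                    "ci_high": float(np.exp(b + z * se)),
                    "p": float(pvals[name]),
                }
            )
    table = pd.DataFrame(rows, columns=["variable", "or_", "ci_low", "ci_high", "p"])
    fit = LogisticFit(
        table=table,
        converged=converged,
        log_likelihood=llf,
        separation=separation,
        n_obs=len(df),
    )
    fit.intercept = float(params["const"]) if "const" in params else float("nan")
    return fit


# --------------------------------------------------------------------------
# ROC analysis


@dataclass
class RocSummary:
    """ROC headline numbers: AUC with DeLong 95% CI and the Youden-optimal
    operating point (threshold in score units; sensitivity/specificity in %)."""

    auc: float
    auc_ci_low: float
    auc_ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    direction: str  # "lower-is-positive" | "higher-is-positive"
    n_positive: int = 0
    n_negative: int = 0
    curve: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def roc_auc(scores, outcome) -> float:
    """AUC via the rank (Mann-Whitney) construction with midrank ties:
    the probability a random positive outscores a random negative
    (ties count one half).  Direction: higher score = positive."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise UndefinedAUCError("both outcome classes must be present")
    ranks = _midranks(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float, level=0.95):
    """DeLong variance of the AUC from the structural components
    V10 (per positive) and V01 (per negative)."""
    m, n = len(pos), len(neg)
    all_s = np.concatenate([pos, neg])
    r_all = _midranks(all_s)
    r_pos = _midranks(pos)
    r_neg = _midranks(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = sps.norm.ppf(0.5 + level / 2.0)
    return max(0.0, auc - z * se), min(1.0, auc + z * se)


def youden_threshold(scores, outcome) -> tuple[float, float, float]:
    """Cut-point maximising Youden's J over the observed score values.

    Direction higher-is-positive: predict positive when score >= threshold.
    Returns (threshold, sensitivity, specificity) with rates as fractions.
    Ties on J are broken toward higher sensitivity, then the lower threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedAUCError("both outcome classes must be present")
    best = None
    for c in np.unique(s):
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        j = sens + spec - 1.0
        key = (j, sens, -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, c, sens, spec = best
    return float(c), sens, spec


def roc_analysis(scores, outcome, direction: str = "higher-is-positive") -> RocSummary:
    """Full ROC analysis of a continuous score against a binary outcome.

    ``direction="lower-is-positive"`` (used for doubling times: shorter
    doubling time predicts metastasis) analyses the negated score internally
    and reports the threshold back on the original scale, so the summary is
    invariant to jointly flipping the score sign and the direction.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    mask = ~np.isnan(s)
    s, y = s[mask], y[mask]
    if direction == "lower-is-positive":
        s_int = -s
    elif direction == "higher-is-positive":
        s_int = s
    else:
        raise ValueError(f"unknown direction {direction!r}")
    auc = roc_auc(s_int, y)
    pos, neg = s_int[y == 1], s_int[y == 0]
    lo, hi = _delong_ci(pos, neg, auc)
    thr_int, sens, spec = youden_threshold(s_int, y)
    threshold = -thr_int if direction == "lower-is-positive" else thr_int
    cuts = np.unique(s_int)
    curve = pd.DataFrame(
        {
            "threshold": -cuts if direction == "lower-is-positive" else cuts,
            "tpr": [float(np.mean(pos >= c)) for c in cuts],
            "fpr": [float(np.mean(neg >= c)) for c in cuts],
        }
    )
    return RocSummary(
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        threshold=float(threshold),
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        direction=direction,
        n_positive=int(len(pos)),
        n_negative=int(len(neg)),
        curve=curve,
    )
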