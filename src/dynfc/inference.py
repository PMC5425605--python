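"""Group-level statistics: design construction, OLS regressions,
one-sample t-tests, and Benjamini-Hochberg FDR adjustment.

Two designs are supported.  The *ctq* model enters the five Childhood
Trauma Questionnaire subscales simultaneously (log-transformed then
z-scored; subscale scores are bounded below by 5, so the log is always
defined) together with z-scored age, verbal IQ, and mean framewise
displacement.  The *group* model replaces the subscales with a 0/1
assault-exposure dummy and keeps the same three covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["SubjectRecord", "RegressionResult", "build_design", "ols_fit",
           "one_sample_t", "fdr_adjust", "CTQ_COLUMNS", "COVARIATE_COLUMNS"]

CTQ_COLUMNS = ["ctq_emotional_abuse", "ctq_physical_abuse", "ctq_sexual_abuse",
               "ctq_emotional_neglect", "ctq_physical_neglect"]
COVARIATE_COLUMNS = ["age", "verbal_iq", "mean_fd"]


@dataclass
class SubjectRecord:
    """One subject's covariates (a row of the cohort table)."""

    subject_id: str
    group: str  # "control" | "assaulted"
    age: float
    verbal_iq: float
    ctq_emotional_abuse: float
    ctq_physical_abuse: float
    ctq_sexual_abuse: float
    ctq_emotional_neglect: float
    ctq_physical_neglect: float
    mean_fd: float


@dataclass
class RegressionResult:
    """Per-predictor OLS estimates for one outcome."""

    table: pd.DataFrame  # columns: term, coef, se, t, p
    df_resid: int
    outcome: str = ""

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "coef"])

    def p(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd <= 0:
        raise ValueError(f"column {name!r} is constant after transform")
    return (x - x.mean()) / sd


def build_design(records, model: str = "ctq", log_ctq: bool = True) -> pd.DataFrame:
    """Design matrix (with intercept) aligned to the record order.

    ``records`` is a DataFrame or list of :class:`SubjectRecord`.  The
    *ctq* model has 9 columns (intercept + five subscales + three
    covariates); the *group* model has 5 (intercept + assault dummy +
    three covariates).  ``log_ctq=False`` skips the log transform of the
    subscales, keeping only the z-scoring.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.__dict__ for r in records])
    X = pd.DataFrame(index=records.index)
    X["intercept"] = 1.0
    if model == "ctq":
        for col in CTQ_COLUMNS:
            vals = records[col].to_numpy(float)
            if log_ctq:
                vals = np.log(vals)
            X[col] = _zscore(vals, col)
    elif model == "group":
        dummy = (records["group"] == "assaulted").to_numpy(float)
        if dummy.std() <= 0:
            raise ValueError("column 'group' is constant: cannot code the "
                             "assault dummy")
        X["assaulted"] = dummy
    else:
        raise ValueError(f"unknown model {model!r}")
    for col in COVARIATE_COLUMNS:
        X[col] = _zscore(records[col].to_numpy(float), col)
    if len(records) < X.shape[1] + 2:
        raise ValueError(f"need at least {X.shape[1] + 2} complete cases "
                         f"for the {model} model, got {len(records)}")
    return X


def ols_fit(y, X: pd.DataFrame, outcome: str = "") -> RegressionResult:
    """Ordinary least squares with two-sided t-based p-values."""
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        corr = np.corrcoef(Xv[:, 1:], rowvar=False)
        names = list(X.columns[1:]) if isinstance(X, pd.DataFrame) else []
        bad = [names[i] for i in range(len(names))
               if np.any(np.abs(corr[i, :i]) > 1 - 1e-10)] or names
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, Xv).fit()
    terms = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{i}" for i in range(Xv.shape[1])]
    table = pd.DataFrame({"term": terms, "coef": fit.params, "se": fit.bse,
                          "t": fit.tvalues, "p": fit.pvalues})
    return RegressionResult(table=table, df_resid=int(fit.df_resid),
                            outcome=outcome)


def one_sample_t(values) -> tuple[float, int, float]:
    """One-sample t-test of the mean against zero.

    Returns ``(t, df, p)``; zero-variance input yields an infinite t
    (signed by the mean) with p = 0 flagged by the infinity itself.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 3:
        raise ValueError("need at least 3 finite values")
    if vals.std(ddof=1) <= 0:
        t = np.inf * np.sign(vals.mean()) if vals.mean() != 0 else 0.0
        return float(t), vals.size - 1, 0.0 if np.isinf(t) else 1.0
    res = stats.ttest_1samp(vals, 0.0)
    return float(res.statistic), vals.size - 1, float(res.pvalue)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]
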