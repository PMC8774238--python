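"""Univariate screening, ROC characterization, and the prediction model.

The screening stage compares each shortlisted feature between the two classes
with the Mann-Whitney U test under a Bonferroni-corrected threshold.  Each
significant feature is characterized by ROC analysis (rank-based AUC, DeLong
standard error against AUC = 0.5, Youden-optimal cutoff, exact binomial
confidence intervals).  The multivariate stage is an "enter"-type multiple
regression: the 0/1 class outcome is regressed on all significant features
simultaneously by ordinary least squares (a linear probability model, which
is what the clinical statistics packages this mirrors produce for "multiple
regression"), and the fitted values feed a final ROC analysis of the combined
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .selection import (
    FeatureMatrix,
    SelectionResult,
    merge_selections,
    select_fisher,
    select_poe_acc,
)

__all__ = [
    "mann_whitney",
    "bonferroni_threshold",
    "RocResult",
    "roc_analysis",
    "RegressionReport",
    "fit_enter_model",
    "prediction_roc",
    "StudyReport",
    "run_study",
]

#: sample-size bound below which the exact Mann-Whitney null is used
EXACT_MW_LIMIT = 16


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for ``x``) and two-sided p-value.

    ``U = sum over pairs of [x > y] + 0.5 [x == y]``.  The p-value is exact
    (full enumeration of label assignments) when ``n_x + n_y <= 16`` and there
    are no ties, otherwise a normal approximation with tie-corrected variance
    and continuity correction is used.  If every value in both groups is
    identical the test is vacuous and ``p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold ``alpha / m``."""
    if not 0 < alpha < 1 or m < 1:
        raise ValueError("need 0 < alpha < 1 and m >= 1")
    return alpha / m


# ----------------------------------------------------------------------------
# ROC analysis
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    """ROC characterization of one score against binary labels.

    ``direction`` records whether the positive class takes higher or lower
    scores; ``cutoff`` is then read as "positive if score > cutoff" or
    "positive if score <= cutoff" respectively.  ``auc_ci`` is a binomial
    exact (Clopper-Pearson on correctly ordered pairs) 95% interval;
    ``p_vs_half`` is the DeLong test against AUC = 0.5.  Sensitivity and
    specificity at the Youden-optimal cutoff carry exact 95% intervals.
    """

    auc: float
    auc_se: float
    auc_ci: tuple[float, float]
    p_vs_half: float
    youden: float
    cutoff: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    direction: Literal["greater_is_positive", "lesser_is_positive"]
    n_positive: int
    n_negative: int

    @property
    def criterion(self) -> str:
        op = ">" if self.direction == "greater_is_positive" else "<="
        return f"{op}{self.cutoff:g}"


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = sps.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def _delong_se(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels]
    neg = scores[~labels]
    # structural components: placement of each observation against the
    # opposite class
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = 0.0
    if pos.size > 1:
        var += np.var(v10, ddof=1) / pos.size
    if neg.size > 1:
        var += np.var(v01, ddof=1) / neg.size
    return float(np.sqrt(var))


def _clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1 - level
    lo = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


def roc_analysis(
    scores,
    labels,
    positive_direction: Literal["auto", "greater", "lesser"] = "auto",
) -> RocResult:
    """Full ROC characterization with a Youden-optimal operating point."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    auc = _auc_rank(scores, labels)
    if positive_direction == "auto":
        direction = "greater_is_positive" if auc >= 0.5 else "lesser_is_positive"
    else:
        direction = f"{positive_direction}_is_positive"
    eff = scores if direction == "greater_is_positive" else -scores
    auc_eff = _auc_rank(eff, labels)
    se = _delong_se(eff, labels)
    if se == 0:
        p = 0.0 if auc_eff != 0.5 else 1.0
    else:
        p = 2 * sps.norm.sf(abs(auc_eff - 0.5) / se)

    n_pairs = n_pos * n_neg
    concordant = int(round(auc_eff * n_pairs))
    auc_ci = _clopper_pearson(concordant, n_pairs)

    # Youden-optimal cutoff over observed criterion values ("positive if
    # effective score > t"); lowest criterion wins ties
    pos = np.sort(eff[labels])
    neg = np.sort(eff[~labels])
    cand = np.unique(eff)
    sens = 1.0 - np.searchsorted(pos, cand, side="right") / n_pos
    spec = np.searchsorted(neg, cand, side="right") / n_neg
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (lowest t) maximizer
    cutoff_eff = float(cand[best])
    tp = int(round(sens[best] * n_pos))
    tn = int(round(spec[best] * n_neg))
    cutoff = cutoff_eff if direction == "greater_is_positive" else -cutoff_eff

    return RocResult(
        auc=float(auc_eff),
        auc_se=se,
        auc_ci=auc_ci,
        p_vs_half=float(p),
        youden=float(j[best]),
        cutoff=cutoff,
        sensitivity=float(sens[best]),
        sensitivity_ci=_clopper_pearson(tp, n_pos),
        specificity=float(spec[best]),
        specificity_ci=_clopper_pearson(tn, n_neg),
        direction=direction,
        n_positive=n_pos,
        n_negative=n_neg,
    )


# ----------------------------------------------------------------------------
# Multivariate prediction model
# ----------------------------------------------------------------------------


@dataclass
class RegressionReport:
    """Enter-model multiple regression of the 0/1 outcome on all predictors.

    ``table`` has one row per predictor: coefficient, std_error, t, p,
    r_partial, r_semipartial, VIF.  ``mcc`` is the multiple correlation
    coefficient ``sqrt(R^2)``; ``predicted`` are the fitted values used for
    the combined-model ROC.
    """

    table: pd.DataFrame
    intercept: float
    r2: float
    r2_adjusted: float
    mcc: float
    predicted: np.ndarray
    df_resid: int


def fit_enter_model(M: FeatureMatrix, outcome=None) -> RegressionReport:
    """Ordinary least squares of the 0/1 outcome on all features at once."""
    import statsmodels.api as sm

    y = M.labels.astype(float) if outcome is None else np.asarray(outcome, dtype=float)
    X = M.values
    names = list(M.features)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more subjects ({n}) than predictors + 1 ({p + 1})")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError(
            "exact collinearity among predictors: " + ", ".join(_dependent_columns(X, names))
        )
    fit = sm.OLS(y, design).fit()
    df_resid = int(fit.df_resid)
    r2 = float(fit.rsquared)

    rows = []
    for j, name in enumerate(names):
        t = float(fit.tvalues[j + 1])
        others = np.delete(X, j, axis=1)
        aux = sm.OLS(X[:, j], sm.add_constant(others, has_constant="add")).fit()
        vif = np.inf if aux.rsquared >= 1.0 else 1.0 / (1.0 - aux.rsquared)
        rows.append(
            {
                "predictor": name,
                "coefficient": float(fit.params[j + 1]),
                "std_error": float(fit.bse[j + 1]),
                "t": t,
                "p": float(fit.pvalues[j + 1]),
                "r_partial": t / np.sqrt(t**2 + df_resid),
                "r_semipartial": t * np.sqrt(1.0 - r2) / np.sqrt(df_resid),
                "vif": float(vif) if p > 1 else 1.0,
            }
        )
    return RegressionReport(
        table=pd.DataFrame(rows).set_index("predictor"),
        intercept=float(fit.params[0]),
        r2=r2,
        r2_adjusted=float(fit.rsquared_adj),
        mcc=float(np.sqrt(r2)),
        predicted=np.asarray(fit.fittedvalues, dtype=float),
        df_resid=df_resid,
    )


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    dep = []
    for j in range(X.shape[1]):
        others = np.column_stack([np.delete(X, j, axis=1), np.ones(X.shape[0])])
        resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        if np.allclose(resid, 0, atol=1e-10 * max(1.0, np.abs(X[:, j]).max())):
            dep.append(names[j])
    return dep or names


def prediction_roc(report: RegressionReport, labels) -> RocResult:
    """ROC of the combined model's fitted values against the class labels."""
    return roc_analysis(report.predicted, labels)


# ----------------------------------------------------------------------------
# The full screening -> ROC -> model workflow
# ----------------------------------------------------------------------------


@dataclass
class StudyReport:
    """All stages of the selection/screening/prediction workflow."""

    fisher: SelectionResult
    poe_acc: SelectionResult
    union: list[str]
    overlap: list[str]
    univariate: pd.DataFrame
    m_tests: int
    threshold: float
    significant: list[str]
    roc_per_feature: dict[str, RocResult]
    regression: RegressionReport | None
    prediction: RocResult | None
    status: str
    flag_threshold: float | None = None

    def to_dict(self) -> dict:
        def roc_dict(r: RocResult) -> dict:
            return {
                "auc": r.auc,
                "auc_ci": list(r.auc_ci),
                "p_vs_half": r.p_vs_half,
                "youden": r.youden,
                "criterion": r.criterion,
                "sensitivity": r.sensitivity,
                "sensitivity_ci": list(r.sensitivity_ci),
                "specificity": r.specificity,
                "specificity_ci": list(r.specificity_ci),
            }

        out = {
            "status": self.status,
            "selection": {
                "fisher": self.fisher.names,
                "poe_acc": self.poe_acc.names,
                "union": self.union,
                "overlap": self.overlap,
            },
            "univariate": self.univariate.reset_index().to_dict(orient="records"),
            "m_tests": self.m_tests,
            "threshold": self.threshold,
            "significant": self.significant,
            "roc": {k: roc_dict(v) for k, v in self.roc_per_feature.items()},
        }
        if self.regression is not None:
            out["regression"] = {
                "r2": self.regression.r2,
                "r2_adjusted": self.regression.r2_adjusted,
                "mcc": self.regression.mcc,
                "intercept": self.regression.intercept,
                "table": self.regression.table.reset_index().to_dict(orient="records"),
            }
            if self.flag_threshold is not None:
                # post-hoc flagging only; predictors are never dropped
                out["regression"]["flag_threshold"] = self.flag_threshold
                out["regression"]["flagged_predictors"] = [
                    name
                    for name, row in self.regression.table.iterrows()
                    if row["p"] > self.flag_threshold
                ]
        if self.prediction is not None:
            out["prediction_roc"] = roc_dict(self.prediction)
        return out


def run_study(
    M: FeatureMatrix,
    covariates: pd.DataFrame | None = None,
    k: int = 10,
    alpha: float = 0.05,
    extra_tests: int | None = None,
    flag_threshold: float | None = None,
) -> StudyReport:
    """Selection (both methods) -> union -> Mann-Whitney + Bonferroni ->
    per-feature ROC -> enter model -> combined-model ROC.

    ``extra_tests`` widens the Bonferroni divisor beyond the selected-feature
    union; it defaults to the number of covariate columns, or 2 (age and sex)
    when no covariates are given — the convention of the study design this
    workflow mirrors.  If no feature survives the corrected threshold the
    report stops after the univariate stage with an explicit status.
    """
    fisher = select_fisher(M, k=k)
    poe_acc = select_poe_acc(M, k=k)
    union, overlap = merge_selections(fisher, poe_acc)

    if extra_tests is None:
        extra_tests = covariates.shape[1] if covariates is not None else 2
    m = len(union) + extra_tests
    threshold = bonferroni_threshold(alpha, m)

    pos, neg = M.labels, ~M.labels
    rows = []
    for name in union:
        col = M.column(name)
        _, p = mann_whitney(col[pos], col[neg])
        q_pos = np.percentile(col[pos], [25, 50, 75])
        q_neg = np.percentile(col[neg], [25, 50, 75])
        rows.append(
            {
                "feature": name,
                "p_value": p,
                "median_pos": q_pos[1],
                "iqr_pos": (q_pos[0], q_pos[2]),
                "median_neg": q_neg[1],
                "iqr_neg": (q_neg[0], q_neg[2]),
                "significant": p < threshold,
            }
        )
    univariate = pd.DataFrame(rows).set_index("feature")
    significant = [n for n in union if univariate.loc[n, "significant"]]

    roc_per_feature = {
        name: roc_analysis(M.column(name), M.labels) for name in significant
    }
    regression = prediction = None
    status = "complete"
    if not significant:
        status = "no feature significant after Bonferroni correction"
    elif len(M.subjects) > len(significant) + 1:
        sub = FeatureMatrix(
            subjects=M.subjects,
            features=significant,
            values=np.column_stack([M.column(n) for n in significant]),
            labels=M.labels,
        )
        regression = fit_enter_model(sub)
        prediction = prediction_roc(regression, M.labels)
    else:
        status = "too few subjects for the multivariate stage"

    return StudyReport(
        fisher=fisher,
        poe_acc=poe_acc,
        union=union,
        overlap=overlap,
        univariate=univariate,
        m_tests=m,
        threshold=threshold,
        significant=significant,
        roc_per_feature=roc_per_feature,
        regression=regression,
        prediction=prediction,
        status=status,
        flag_threshold=flag_threshold,
    )
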