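"""Cohort statistics: clustered-eye GEE, pairwise contrasts, ROC/AUC, Spearman.

Group comparisons use a generalized estimating equation (GEE) with identity
link, Gaussian working variance and exchangeable working correlation, with
the patient as the cluster so fellow eyes of one patient are not treated as
independent; inference uses the robust (sandwich) covariance.  All group
models adjust for age (centered) and sex.  Diagnostic performance is
summarized by the ROC AUC with a DeLong 95% CI, and monotone associations by
the Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

import statsmodels.api as sm

__all__ = [
    "GEEResult",
    "ROCResult",
    "SingularDesignError",
    "ConstantInputError",
    "gee_fit",
    "pairwise_contrasts",
    "roc_auc",
    "spearman",
]


class SingularDesignError(ValueError):
    """Raised when the GEE design matrix is rank deficient."""


class ConstantInputError(ValueError):
    """Raised when a correlation input has zero variance."""


@dataclass
class GEEResult:
    params: pd.Series
    robust_se: pd.Series
    z: pd.Series
    p: pd.Series
    working_correlation: float
    n_clusters: int
    n_observations: int
    _result: object = None  # statsmodels handle, for contrasts

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = sps.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"low": self.params - q * self.robust_se,
             "high": self.params + q * self.robust_se}
        )


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    polarity: int = 1  # -1 when scores were negated so that AUC >= 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.auc <= self.ci_high <= 1):
            raise ValueError("CI must bracket the AUC inside [0, 1]")


def _design(table: pd.DataFrame, outcome: str, predictors: list[str],
            covariates: tuple[str, ...]) -> tuple[pd.DataFrame, pd.Series]:
    cols = {"Intercept": np.ones(len(table))}
    for p in predictors:
        cols[p] = np.asarray(table[p], dtype=float)
    if "age" in covariates:
        age = np.asarray(table["age"], dtype=float)
        cols["age_c"] = age - age.mean()
    if "sex" in covariates:
        sex = table["sex"]
        cols["sex_male"] = (np.asarray(sex) == "M").astype(float) \
            if sex.dtype == object else np.asarray(sex, dtype=float)
    X = pd.DataFrame(cols, index=table.index)
    y = pd.Series(np.asarray(table[outcome], dtype=float), index=table.index)
    return X, y


def gee_fit(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    covariates: tuple[str, ...] = ("age", "sex"),
    cluster: str = "patient_id",
    correlation: str = "exchangeable",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> GEEResult:
    """Fit the marginal Gaussian GEE of ``outcome`` on numeric ``predictors``.

    ``predictors`` are numeric columns (e.g. 0/1 group indicators); age and
    sex enter as configured covariates.  Rows with missing values are
    dropped.  Raises :class:`SingularDesignError` on rank-deficient designs
    and ``ValueError`` when fewer than two clusters remain.
    """
    needed = [outcome, cluster, *predictors] + \
        [c for c in ("age", "sex") if c in covariates]
    sub = table[needed].dropna()
    if sub[cluster].nunique() < 2:
        raise ValueError("need at least 2 clusters")
    X, y = _design(sub, outcome, predictors, covariates)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError(f"design matrix is rank deficient: {list(X)}")
    cov = sm.cov_struct.Exchangeable() if correlation == "exchangeable" \
        else sm.cov_struct.Independence()
    model = sm.GEE(y, X, groups=sub[cluster], family=sm.families.Gaussian(),
                   cov_struct=cov)
    res = model.fit(maxiter=maxiter, ctol=tol)
    if not res.converged:
        raise RuntimeError("GEE did not converge")
    rho = float(cov.dep_params) if correlation == "exchangeable" else 0.0
    return GEEResult(
        params=res.params, robust_se=res.bse, z=res.tvalues, p=res.pvalues,
        working_correlation=rho, n_clusters=int(sub[cluster].nunique()),
        n_observations=int(len(sub)), _result=res,
    )


def pairwise_contrasts(
    table: pd.DataFrame,
    outcome: str,
    group: str = "group",
    groups: tuple[str, str, str] = ("normal", "NPDR", "PDR"),
    covariates: tuple[str, ...] = ("age", "sex"),
    cluster: str = "patient_id",
) -> dict[str, float]:
    """Adjusted three-group comparison of one biomarker.

    Fits a single GEE with indicator coding (first group is the reference)
    and reports Wald p-values: the overall 2-df group test and the three
    pairwise contrasts P1 (ref vs second), P2 (ref vs third), P3 (second vs
    third).  No multiplicity correction is applied.
    """
    present = set(table[group].dropna().unique())
    missing = [g for g in groups if g not in present]
    if missing:
        raise ValueError(f"missing groups: {missing}")
    tab = table[table[group].isin(groups)].copy()
    g1, g2 = f"is_{groups[1]}", f"is_{groups[2]}"
    tab[g1] = (tab[group] == groups[1]).astype(float)
    tab[g2] = (tab[group] == groups[2]).astype(float)
    fit = gee_fit(tab, outcome, [g1, g2], covariates=covariates, cluster=cluster)
    res = fit._result
    k = len(fit.params)
    idx1 = list(fit.params.index).index(g1)
    idx2 = list(fit.params.index).index(g2)
    c_overall = np.zeros((2, k)); c_overall[0, idx1] = 1; c_overall[1, idx2] = 1
    c_diff = np.zeros((1, k)); c_diff[0, idx2] = 1; c_diff[0, idx1] = -1
    return {
        "p_overall": float(res.wald_test(c_overall, scalar=True).pvalue),
        "P1": float(fit.p[g1]),
        "P2": float(fit.p[g2]),
        "P3": float(res.wald_test(c_diff, scalar=True).pvalue),
        "coef_1": float(fit.params[g1]),
        "coef_2": float(fit.params[g2]),
        "n": fit.n_observations,
    }


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC via mid-rank placement components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)

    def midrank(x):
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(len(x))
        sx = x[order]
        i = 0
        while i < len(x):
            j = i
            while j < len(x) and sx[j] == sx[i]:
                j += 1
            ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
            i = j
        return ranks

    allx = np.concatenate([pos, neg])
    r_all = midrank(allx)
    r_pos = midrank(pos)
    r_neg = midrank(neg)
    v10 = (r_all[:m] - r_pos) / n            # placement of positives
    v01 = 1.0 - (r_all[m:] - r_neg) / m      # placement of negatives
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC with a DeLong 95% CI.

    The AUC equals the Mann-Whitney concordance probability with ties
    counted 1/2.  Polarity is chosen automatically so the reported AUC is
    >= 0.5 (recorded in ``polarity``); both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes 0 and 1")
    polarity = 1
    auc = float(roc_auc_score(labels, scores))
    if auc < 0.5:
        polarity, scores, auc = -1, -scores, 1.0 - auc
    fpr, tpr, _ = roc_curve(labels, scores)
    se = float(np.sqrt(_delong_variance(scores, labels)))
    q = sps.norm.ppf(0.975)
    lo = float(np.clip(auc - q * se, 0, auc))
    hi = float(np.clip(auc + q * se, auc, 1))
    return ROCResult(auc=auc, ci_low=lo, ci_high=hi, fpr=fpr, tpr=tpr,
                     polarity=polarity)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on mid-ranks) with a t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
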