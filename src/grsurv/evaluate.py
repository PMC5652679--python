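"""Incremental predictive value of the GRS via paired ROC analysis.

Two nested logistic models for BCR are fit on identical subjects — clinical
covariates only, and clinical + GRS — and their in-sample ROC AUCs are
compared with the structural-components (DeLong) test for correlated AUCs,
with a subject-resampling bootstrap as an alternative.  AUC is the
Mann-Whitney probability that a random case outranks a random control (ties
counted 1/2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import ValidationError
from .survival import CLINICAL_COVARIATES, _model_frame

Z_95 = stats.norm.ppf(0.975)


def roc_auc(scores, labels) -> float:
    """AUC = Mann-Whitney U / (n1 * n0), ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.size != labels.size:
        raise ValidationError("scores and labels differ in length")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both outcome classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_cov(scores_stack: np.ndarray, labels: np.ndarray):
    """AUCs and their covariance matrix by the structural-components method.

    ``scores_stack`` is (k, n): k score vectors over the same n subjects.
    """
    pos = labels == 1
    m = int(pos.sum())
    n = int((~pos).sum())
    k = scores_stack.shape[0]
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        x = scores_stack[r, pos]
        y = scores_stack[r, ~pos]
        tz = _midrank(np.concatenate([x, y]))
        tx = _midrank(x)
        ty = _midrank(y)
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
    s10 = np.cov(v10, ddof=1) if m > 1 else np.zeros((k, k))
    s01 = np.cov(v01, ddof=1) if n > 1 else np.zeros((k, k))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


@dataclass
class ROCComparison:
    auc_clinical: float
    auc_genetic: float
    auc_diff: float
    ci_diff: tuple[float, float]
    p_value: float
    n: int
    method: str


def compare_auc_paired(
    scores_a,
    scores_b,
    labels,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCComparison:
    """Two-sided test of AUC(b) - AUC(a) on the same subjects.

    ``delong`` uses the structural-components variance of the paired AUC
    difference; ``bootstrap`` resamples subjects (stratified by outcome) and
    uses the bootstrap SE.  Identical score vectors give diff 0 and p = 1.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    if not (scores_a.size == scores_b.size == labels.size):
        raise ValidationError("paired AUC comparison needs equal-length inputs")
    auc_a = roc_auc(scores_a, labels)
    auc_b = roc_auc(scores_b, labels)
    diff = auc_b - auc_a

    if method == "delong":
        _, cov = _delong_cov(np.vstack([scores_a, scores_b]), labels)
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
        if var <= 0:
            p = 1.0 if diff == 0 else float("nan")
            half = 0.0
        else:
            z = diff / math.sqrt(var)
            p = float(2 * stats.norm.sf(abs(z)))
            half = Z_95 * math.sqrt(var)
        ci = (diff - half, diff + half)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx_pos = np.flatnonzero(labels == 1)
        idx_neg = np.flatnonzero(labels == 0)
        diffs = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate(
                [
                    rng.choice(idx_pos, idx_pos.size, replace=True),
                    rng.choice(idx_neg, idx_neg.size, replace=True),
                ]
            )
            diffs[b] = roc_auc(scores_b[take], labels[take]) - roc_auc(
                scores_a[take], labels[take]
            )
        sd = diffs.std(ddof=1)
        if sd == 0:
            p = 1.0 if diff == 0 else float("nan")
        else:
            p = float(2 * stats.norm.sf(abs(diff / sd)))
        ci = tuple(np.quantile(diffs, [0.025, 0.975]))
    else:
        raise ValidationError(f"unknown method {method!r}")

    return ROCComparison(
        auc_clinical=auc_a,
        auc_genetic=auc_b,
        auc_diff=diff,
        ci_diff=ci,
        p_value=p,
        n=int(labels.size),
        method=method,
    )


def _logit_probs(X: pd.DataFrame, y: np.ndarray) -> tuple[np.ndarray, bool]:
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
        return np.asarray(fit.predict(Xc)), False
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        # fall back to a heavily ridge-stabilized fit, flagged as separated
        fit = sm.Logit(y, Xc).fit_regularized(alpha=1e-4, disp=0)
        return np.asarray(fit.predict(Xc)), True


def fit_evaluation_models(
    phenotypes: pd.DataFrame,
    scores: pd.DataFrame,
    gleason_coding: str = "binary",
    cv_folds: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted BCR probabilities from the clinical and clinico-genetic
    logistic models on identical subjects.

    Returns a frame with sample_id, bcr_event, p_clinical, p_genetic and a
    ``separation`` flag.  Probabilities are in-sample by default (matching
    the usual apparent-AUC procedure); ``cv_folds`` switches to stratified
    cross-validated out-of-sample probabilities, which are less optimistic.
    """
    merged = phenotypes.merge(scores[["sample_id", "grs"]], on="sample_id", how="inner")
    if len(merged) != len(phenotypes) or len(merged) != len(scores):
        raise ValidationError("phenotypes and scores cover different samples")
    df = _model_frame(merged, gleason_coding)
    y = df["bcr_event"].to_numpy(int)
    X_clin = df[CLINICAL_COVARIATES]
    X_gen = df[CLINICAL_COVARIATES + ["grs"]]

    if cv_folds is None:
        p_clin, sep1 = _logit_probs(X_clin, y)
        p_gen, sep2 = _logit_probs(X_gen, y)
    else:
        from sklearn.model_selection import StratifiedKFold

        p_clin = np.empty(len(df))
        p_gen = np.empty(len(df))
        sep1 = sep2 = False
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        for train, test in skf.split(X_clin, y):
            for X, out in ((X_clin, p_clin), (X_gen, p_gen)):
                Xc = sm.add_constant(X.astype(float), has_constant="add")
                fit = sm.Logit(y[train], Xc.iloc[train]).fit(disp=0, maxiter=100)
                out[test] = np.asarray(fit.predict(Xc.iloc[test]))
    return pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "bcr_event": y,
            "p_clinical": p_clin,
            "p_genetic": p_gen,
            "separation": bool(sep1 or sep2),
        }
    )


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC coordinates (threshold, sensitivity, 1 - specificity) for a TSV."""
    fpr, tpr, thresh = roc_curve(np.asarray(labels, int), np.asarray(scores, float))
    return pd.DataFrame(
        {"threshold": thresh, "sensitivity": tpr, "one_minus_specificity": fpr}
    )
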