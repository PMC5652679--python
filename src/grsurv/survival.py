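"""Kaplan-Meier estimation, log-rank testing, and Cox proportional hazards.

Follow-up is in months; events are biochemical recurrences.  The Kaplan-Meier
curve and log-rank test are computed with lifelines; the Cox model is a
Newton-Raphson maximization of the partial likelihood written here so that
both Efron (default) and Breslow tie handling are available, along with the
score test at beta = 0 (which, for a single binary covariate with Breslow
ties, is identical to the log-rank statistic).

The two standard nested models for this cohort are the clinical model (age,
initial PSA, high-grade Gleason, extracapsular extension, seminal vesicle
invasion, positive surgical margin) and the clinico-genetic model adding the
genetic risk score as a continuous covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import CollinearityError, ValidationError

Z_95 = stats.norm.ppf(0.975)

CLINICAL_COVARIATES = ["age_years", "psa_ng_ml", "gleason_high", "ece", "svi", "psm"]


@dataclass
class KMCurve:
    """Product-limit survival estimate over the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function lookup: S(t) = S at the last event time <= t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "survival": self.survival,
                "greenwood_variance": self.variance,
            }
        )


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator; subjects censored at an event time are counted
    at risk at that time (censoring after events at ties)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValidationError("empty input to km_estimate")
    if times.size != events.size:
        raise ValidationError("times and events differ in length")
    if (times <= 0).any():
        raise ValidationError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    t = event_rows.index.to_numpy(float)
    d = event_rows["observed"].to_numpy(float)
    n = event_rows["at_risk"].to_numpy(float)
    surv = np.cumprod(1.0 - d / n)
    gw = surv**2 * np.cumsum(d / (n * (n - d)))
    return KMCurve(t, n, d, surv, gw)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """k-group log-rank test (hypergeometric variance); returns (chi2, p)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValidationError("log-rank test needs at least two groups")
    if (counts < 1).any():
        raise ValidationError("every group needs at least one subject")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxModel:
    """Fitted proportional-hazards model summary."""

    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    ties_method: str
    log_likelihood: float
    converged: bool
    n: int
    n_events: int
    flags: str = ""

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coef - Z_95 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coef + Z_95 * self.se)

    @property
    def p_values(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.coef / self.se))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.coef,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            }
        )


def _prepare_cox(X, times, events):
    X = pd.DataFrame(X)
    names = list(X.columns.astype(str))
    x = X.to_numpy(float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if x.shape[0] != times.size or times.size != events.size:
        raise ValidationError("covariates, times and events differ in length")
    if events.sum() < 1:
        raise ValidationError("Cox fit needs at least one event")
    sd = x.std(axis=0)
    constant = [names[j] for j in range(x.shape[1]) if sd[j] == 0]
    if constant:
        raise ValidationError(f"constant covariates: {constant}")
    if x.shape[1] > 1:
        corr = np.corrcoef(x, rowvar=False)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if abs(corr[i, j]) > 1 - 1e-10:
                    raise CollinearityError(
                        f"covariates {names[i]!r} and {names[j]!r} are collinear"
                    )
    order = np.argsort(times, kind="stable")
    return names, x[order], times[order], events[order]


def _cox_ll_grad_hess(beta, x, times, events, ties):
    """Log partial likelihood, gradient and Hessian (Efron or Breslow ties)."""
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # iterate distinct event times from largest to smallest, accumulating the
    # risk-set sums S0 = sum w, S1 = sum w*x, S2 = sum w*x x'
    s0, s1, s2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = n - 1
    unique_times = np.unique(times[events == 1])
    for t in unique_times[::-1]:
        while i >= 0 and times[i] >= t:
            s0 += w[i]
            s1 += w[i] * x[i]
            s2 += w[i] * np.outer(x[i], x[i])
            i -= 1
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        xd = x[dead]
        wd = w[dead]
        ll += eta[dead].sum()
        grad += xd.sum(axis=0)
        if ties == "breslow":
            frac = np.zeros(d)
        else:  # efron
            frac = np.arange(d) / d
        d0 = s0 - frac * wd.sum()
        d1 = s1[None, :] - frac[:, None] * (wd @ xd)
        d2 = s2[None, :, :] - frac[:, None, None] * np.einsum("i,ij,ik->jk", wd, xd, xd)
        ll -= np.log(d0).sum()
        grad -= (d1 / d0[:, None]).sum(axis=0)
        mean = d1 / d0[:, None]
        hess -= (d2 / d0[:, None, None]).sum(axis=0)
        hess += np.einsum("lj,lk->jk", mean, mean)
    return ll, grad, hess


def cox_fit(
    X,
    times,
    events,
    ties_method: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxModel:
    """Newton-Raphson maximization of the Cox partial likelihood.

    Non-convergence (including monotone likelihood from separation) returns a
    flagged model with ``converged=False`` rather than raising.
    """
    if ties_method not in ("efron", "breslow"):
        raise ValidationError(f"unknown ties_method {ties_method!r}")
    names, x, t, e = _prepare_cox(X, times, events)
    # center covariates for numerical stability; coefficients are unaffected
    shift = x.mean(axis=0)
    xc = x - shift
    beta = np.zeros(x.shape[1])
    ll, grad, hess = _cox_ll_grad_hess(beta, xc, t, e, ties_method)
    converged = False
    flags = []
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            flags.append("singular_hessian")
            break
        new_beta = beta - step
        new_ll, new_grad, new_hess = _cox_ll_grad_hess(new_beta, xc, t, e, ties_method)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
            new_beta = (beta + new_beta) / 2
            new_ll, new_grad, new_hess = _cox_ll_grad_hess(new_beta, xc, t, e, ties_method)
            halvings += 1
        delta = np.max(np.abs(new_beta - beta))
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if delta < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 50:
            flags.append("monotone_likelihood")
            break
    if not converged and "monotone_likelihood" not in flags and "singular_hessian" not in flags:
        flags.append("not_converged")
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(beta.size, np.nan)
    return CoxModel(
        covariates=names,
        coef=beta,
        se=se,
        ties_method=ties_method,
        log_likelihood=float(ll),
        converged=converged,
        n=len(t),
        n_events=int(e.sum()),
        flags=";".join(flags),
    )


def cox_score_test(X, times, events) -> tuple[float, float]:
    """Score (Rao) test of beta = 0 with Breslow ties; returns (chi2, p).

    For a single binary covariate this statistic coincides with the two-group
    log-rank test.
    """
    names, x, t, e = _prepare_cox(X, times, events)
    beta = np.zeros(x.shape[1])
    _, grad, hess = _cox_ll_grad_hess(beta, x, t, e, "breslow")
    chi2 = float(grad @ np.linalg.solve(-hess, grad))
    p = float(stats.chi2.sf(chi2, df=x.shape[1]))
    return chi2, p


def _model_frame(phenotypes: pd.DataFrame, gleason_coding: str) -> pd.DataFrame:
    df = phenotypes.copy()
    if gleason_coding == "binary":
        df["gleason_high"] = (df["gleason"] >= 8).astype(float)
    elif gleason_coding == "ordinal":
        df["gleason_high"] = df["gleason"].astype(float)
    else:
        raise ValidationError(f"unknown gleason_coding {gleason_coding!r}")
    return df


def fit_bcr_models(
    phenotypes: pd.DataFrame,
    scores: pd.DataFrame,
    gleason_coding: str = "binary",
    ties_method: str = "efron",
) -> tuple[CoxModel, CoxModel]:
    """Fit the clinical and the clinico-genetic Cox models on identical samples.

    The clinical model uses age, PSA, a high-grade Gleason indicator (>= 8 by
    default; ordinal coding available), ECE, SVI and PSM; the clinico-genetic
    model adds the continuous GRS.
    """
    merged = phenotypes.merge(scores[["sample_id", "grs"]], on="sample_id", how="inner")
    if len(merged) != len(phenotypes) or len(merged) != len(scores):
        raise ValidationError("phenotypes and scores cover different samples")
    df = _model_frame(merged, gleason_coding)
    times = df["followup_months"]
    events = df["bcr_event"]
    clinical = cox_fit(df[CLINICAL_COVARIATES], times, events, ties_method)
    genetic = cox_fit(df[CLINICAL_COVARIATES + ["grs"]], times, events, ties_method)
    return clinical, genetic
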