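"""Survival statistics: Kaplan-Meier curves, log-rank tests, Cox models.

The Kaplan-Meier estimator is delegated to lifelines and wrapped with the
Greenwood standard error. The k-group and trend log-rank statistics are
computed from the hypergeometric moments directly (the trend variant, with
integer scores over ordered Immunoscore grades, is not part of lifelines'
standard surface). The Cox model is fit by a Newton iteration on the
partial likelihood with both Efron and Breslow tie handling selectable;
lifelines exposes only Efron weights, and the explicit solver lets the fit
flag monotone-likelihood degeneracies (perfect separation) instead of
silently returning drifting estimates.

Conventions: times are in months and strictly positive; events are 0/1
(1 = death for OS, recurrence-or-death for DFS); all tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import ConvergenceError, DataError

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxModel",
    "km_estimate",
    "logrank_test",
    "logrank_trend",
    "cox_fit",
    "compare_density_groups",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with per-event-time bookkeeping."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray       # censorings in (previous time, this time]
    greenwood_se: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation; S(t) = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "survival": self.survival,
            "at_risk": self.at_risk,
            "events": self.events,
            "censored": self.censored,
            "greenwood_se": self.greenwood_se,
        })


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p: float
    observed: np.ndarray   # per-group observed event counts
    expected: np.ndarray   # per-group expected event counts
    groups: list


@dataclass(frozen=True)
class CoxModel:
    names: list[str]
    log_hr: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    n: int
    n_events: int
    converged: bool
    ties: str

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.names,
            "log_hr": self.log_hr,
            "se": self.se,
            "hr": self.hr,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p": self.p,
        })


def _check_times_events(times, events, allow_zero_events=False):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise DataError("empty survival sample")
    if t.shape != e.shape:
        raise DataError("times and events must have equal length")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise DataError("survival times must be finite and positive")
    if not np.all((e == 0) | (e == 1)):
        raise DataError("event indicators must be 0/1")
    if not allow_zero_events and e.sum() == 0:
        raise DataError("no events observed")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood standard errors.

    Censored observations reduce the risk set without producing steps; with
    no censoring the curve equals 1 minus the empirical CDF.
    """
    t, e = _check_times_events(times, events, allow_zero_events=True)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table  # indexed by observed time, includes t=0 row

    ev = table["observed"].to_numpy(dtype=float)
    keep = ev > 0
    event_times = table.index.to_numpy(dtype=float)[keep]
    d = ev[keep]
    n_at = table["at_risk"].to_numpy(dtype=float)[keep]
    surv = np.array([
        float(kmf.survival_function_.loc[tt].iloc[0]) for tt in event_times
    ])
    # censorings binned into (previous event time, current event time]
    all_times = table.index.to_numpy(dtype=float)
    cens_all = table["censored"].to_numpy(dtype=float)
    censored = np.zeros_like(d)
    prev = -np.inf
    for i, tt in enumerate(event_times):
        censored[i] = cens_all[(all_times > prev) & (all_times <= tt)].sum()
        prev = tt
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_at > d, d / (n_at * (n_at - d)), np.nan)
    se = surv * np.sqrt(np.nancumsum(terms))
    return KMCurve(times=event_times, survival=surv, at_risk=n_at,
                   events=d, censored=censored, greenwood_se=se)


def _logrank_moments(t, e, membership):
    """Observed/expected event counts and hypergeometric covariance.

    ``membership`` is an (n, k) 0/1 matrix. Returns (O, E, V) where V is the
    k x k summed covariance with the standard tie correction.
    """
    ut = np.unique(t[e == 1])
    at_risk = (t[None, :] >= ut[:, None]).astype(float)     # (T, n)
    event_here = ((t[None, :] == ut[:, None]) & (e[None, :] == 1)).astype(float)
    n_at = at_risk.sum(axis=1)
    d_at = event_here.sum(axis=1)
    n_g = at_risk @ membership                               # (T, k)
    d_g = event_here @ membership
    p = n_g / n_at[:, None]
    observed = d_g.sum(axis=0)
    expected = (d_at[:, None] * p).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(n_at > 1, d_at * (n_at - d_at) / (n_at - 1), 0.0)
    # V = sum_t w_t (diag(p_t) - p_t p_t')
    V = np.einsum("t,tg->g", w, p * (1 - p)) * np.eye(membership.shape[1])
    off = -np.einsum("t,tg,th->gh", w, p, p)
    np.fill_diagonal(off, 0.0)
    V = V + off
    return observed, expected, V


def _group_matrix(groups):
    labels = np.asarray(groups)
    uniq = pd.unique(pd.Series(labels))
    try:
        uniq = np.sort(uniq)
    except TypeError:
        pass
    membership = (labels[:, None] == np.asarray(uniq)[None, :]).astype(float)
    return list(uniq), membership


def logrank_test(times, events, groups) -> LogRankResult:
    """Unweighted k-group log-rank test (df = k - 1).

    ``groups`` is a per-sample label vector; at least two non-empty groups
    and one event are required. Ties are handled with the hypergeometric
    variance correction.
    """
    t, e = _check_times_events(times, events)
    labels, membership = _group_matrix(groups)
    if len(labels) < 2:
        raise DataError("log-rank test needs at least two groups")
    if len(np.asarray(groups)) != t.size:
        raise DataError("group labels must match sample length")
    observed, expected, V = _logrank_moments(t, e, membership)
    # drop one group; chi2 = u' V^- u on the rest
    u = (observed - expected)[:-1]
    Vr = V[:-1, :-1]
    sol, *_ = np.linalg.lstsq(Vr, u, rcond=None)
    chi = float(max(u @ sol, 0.0))
    df = len(labels) - 1
    return LogRankResult(
        chi_square=chi, df=df, p=float(stats.chi2.sf(chi, df)),
        observed=observed, expected=expected, groups=labels,
    )


def logrank_trend(times, events, grades) -> LogRankResult:
    """Log-rank test for trend over ordered groups (df = 1).

    Groups are ordered by their (sorted) labels and scored 0..k-1; the
    statistic is (s'(O-E))² / (s'Vs). With two groups this reduces to the
    ordinary two-group log-rank.
    """
    t, e = _check_times_events(times, events)
    labels, membership = _group_matrix(grades)
    if len(labels) < 2:
        raise DataError("trend test needs at least two ordered groups")
    observed, expected, V = _logrank_moments(t, e, membership)
    scores = np.arange(len(labels), dtype=float)
    u = float(scores @ (observed - expected))
    var = float(scores @ V @ scores)
    chi = (u * u / var) if var > 0 else 0.0
    return LogRankResult(
        chi_square=float(chi), df=1, p=float(stats.chi2.sf(chi, 1)),
        observed=observed, expected=expected, groups=labels,
    )


def _partial_loglik(beta, t, e, X, ties):
    """Log partial likelihood with gradient and Hessian.

    Works on the distinct observed times in ascending order: the risk-set
    sums S0 = Σ exp(η), S1 = Σ exp(η) x and S2 = Σ exp(η) x x' are reversed
    cumulative sums of per-time group sums. For a tied event set D of size
    d, Breslow uses the full risk-set sums d times; Efron discounts them by
    l/d of the event-set sums, l = 0..d-1.
    """
    n, p = X.shape
    order = np.argsort(t, kind="mergesort")
    ts_, es_, Xs = t[order], e[order], X[order]
    eta = Xs @ beta
    eta = eta - eta.max()  # overflow guard; cancels in all ratios
    w = np.exp(eta)

    # group boundaries of distinct times in the sorted arrays
    starts = np.flatnonzero(np.r_[True, ts_[1:] != ts_[:-1]])
    xx = (Xs[:, :, None] * Xs[:, None, :]).reshape(n, p * p)

    def revcum(groupsums):
        return np.cumsum(groupsums[::-1], axis=0)[::-1]

    S0 = revcum(np.add.reduceat(w, starts))
    S1 = revcum(np.add.reduceat(w[:, None] * Xs, starts))
    S2 = revcum(np.add.reduceat(w[:, None] * xx, starts))

    we = w * es_
    D0 = np.add.reduceat(we, starts)
    D1 = np.add.reduceat(we[:, None] * Xs, starts)
    D2 = np.add.reduceat(we[:, None] * xx, starts)
    dcount = np.add.reduceat(es_.astype(float), starts)

    ev = es_ == 1
    ll = float(eta[ev].sum())
    grad = Xs[ev].sum(axis=0)
    hess = np.zeros((p, p))

    max_d = int(dcount.max()) if dcount.size else 0
    for l in range(max_d):
        mask = dcount > l
        if ties == "breslow":
            f = np.zeros(mask.sum())
        else:  # efron
            f = l / dcount[mask]
        s0 = S0[mask] - f * D0[mask]
        s1 = S1[mask] - f[:, None] * D1[mask]
        s2 = S2[mask] - f[:, None] * D2[mask]
        ll -= float(np.log(s0).sum())
        m = s1 / s0[:, None]
        grad = grad - m.sum(axis=0)
        hess -= (s2 / s0[:, None]).sum(axis=0).reshape(p, p)
        hess += m.T @ m
    return ll, grad, hess


def cox_fit(
    covariates: pd.DataFrame,
    times,
    events,
    ties: Literal["efron", "breslow"] = "efron",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxModel:
    """Multivariable Cox proportional-hazards fit (partial likelihood).

    ``covariates`` is an n x p DataFrame with named columns. The partial
    likelihood is maximized by Newton iteration (step-halving on decrease)
    until the gradient infinity-norm drops below ``tol`` relative to the
    log-likelihood magnitude, or ``max_iter`` iterations; Efron tie
    handling by default, Breslow selectable. Wald 95%
    confidence intervals are exp(log-HR ± 1.96 SE). Constant columns are
    rejected by name; a monotone likelihood (perfect separation, estimates
    drifting to ±inf) raises :class:`~tilscore.errors.ConvergenceError`
    rather than silently returning.
    """
    if ties not in ("efron", "breslow"):
        raise DataError(f"unknown tie method {ties!r}")
    t, e = _check_times_events(times, events)
    Xdf = pd.DataFrame(covariates).reset_index(drop=True)
    if Xdf.shape[0] != t.size:
        raise DataError("covariate rows must match sample length")
    if Xdf.shape[0] <= Xdf.shape[1]:
        raise DataError("need more samples than covariates")
    for col in Xdf.columns:
        if Xdf[col].nunique(dropna=False) <= 1:
            raise DataError(f"covariate {col!r} is constant")
    X = Xdf.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise DataError("covariates contain missing values")

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _partial_loglik(beta, t, e, X, ties)
    scale = max(1.0, abs(ll))
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol * scale:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular information matrix in Cox fit") from exc
        # step-halving safeguards the Newton update
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, g_new, h_new = _partial_loglik(cand, t, e, X, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10 * scale:
                break
            factor /= 2.0
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if np.max(np.abs(beta)) > 15.0:
            # |log-HR| > 15 (HR beyond e^15) only happens when the partial
            # likelihood is monotone and the estimate drifts to infinity
            raise ConvergenceError(
                "monotone partial likelihood (perfect separation?): "
                "estimates drifting to infinity")
    else:
        if np.max(np.abs(grad)) < tol * scale:
            converged = True
    if not converged:
        warnings.warn("Cox fit did not reach gradient tolerance; "
                      "estimates flagged as non-converged", stacklevel=2)

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = 1.959963984540054
    wald = beta / se
    return CoxModel(
        names=list(Xdf.columns),
        log_hr=beta,
        se=se,
        hr=np.exp(beta),
        ci_lower=np.exp(beta - z * se),
        ci_upper=np.exp(beta + z * se),
        p=2.0 * stats.norm.sf(np.abs(wald)),
        n=int(t.size),
        n_events=int(e.sum()),
        converged=converged,
        ties=ties,
    )


def compare_density_groups(
    densities,
    labels,
    method: Literal["ranksum", "welch"] = "ranksum",
) -> tuple[float, float]:
    """Two-sided two-group comparison of density samples.

    Default is the Wilcoxon rank-sum (Mann-Whitney) test — density
    distributions are right-skewed — with a Welch t alternative. Returns
    (statistic, p). Used for e.g. NAC responders vs non-responders and the
    BCG-exposure null comparisons.
    """
    d = np.asarray(densities, dtype=float)
    lab = np.asarray(labels)
    groups = pd.unique(pd.Series(lab))
    if len(groups) != 2:
        raise DataError(f"need exactly two groups, got {len(groups)}")
    a = d[lab == groups[0]]
    b = d[lab == groups[1]]
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    if method == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise DataError(f"unknown method {method!r}")
    return float(res.statistic), float(min(res.pvalue, 1.0))
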