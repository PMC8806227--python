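"""Self-contained survival statistics.

Implements the estimators every later stage leans on:

* Kaplan–Meier product-limit curves (:func:`km_estimate`);
* the two-group log-rank test (:func:`logrank_test`), 1-df chi-square from
  observed-minus-expected events with hypergeometric variance;
* Cox proportional-hazards regression (:func:`cox_fit`) by Newton–Raphson
  maximization of the partial likelihood with Efron (default) or Breslow
  tie handling, step-halving to keep the partial likelihood non-decreasing,
  Wald confidence intervals and the score test at β = 0 (which, for a single
  binary covariate on tie-free data, coincides with the log-rank statistic);
* cumulative/dynamic time-dependent ROC at a horizon t (:func:`td_roc`):
  cases are events by t, controls are subjects beyond t, censoring handled
  by inverse-probability-of-censoring weights from the Kaplan–Meier estimate
  of the censoring distribution; AUC by trapezoid;
* Youden-J cutoff selection on such a ROC (:func:`optimal_cutoff`).

Not covered: frailty/stratified/time-varying Cox, competing risks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

_Z95 = 1.959963984540054  # normal 97.5% quantile for Wald CIs


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise DomainError("empty survival input")
    if times.shape != events.shape:
        raise DomainError("times and events must have equal length")
    if not (np.isfinite(times).all() and (times > 0).all()):
        raise DomainError("survival times must be finite and > 0")
    if not np.isin(events, (0, 1)).all():
        raise DomainError("event indicators must be 0 or 1")
    return times, events.astype(int)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float, left: bool = False) -> float:
        """S(t) (right-continuous); ``left=True`` gives the left limit S(t−)."""
        side = "left" if left else "right"
        idx = np.searchsorted(self.event_times, t, side=side)
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Censored-only times shrink later risk sets but contribute no survival
    drop, so the curve is reported at event times only.
    """
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    n = len(t_sorted)

    uniq, first_idx = np.unique(t_sorted, return_index=True)
    at_risk_all = n - first_idx  # subjects with time >= uniq[k]
    d = np.array([e_sorted[t_sorted == u].sum() for u in uniq])
    has_event = d > 0
    event_times = uniq[has_event]
    at_risk = at_risk_all[has_event]
    n_events = d[has_event]
    surv = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(event_times=event_times, survival=surv,
                   at_risk=at_risk, events=n_events)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    chi_square: float
    p_value: float


def logrank_test(times, events, group) -> LogrankResult:
    """Two-group log-rank test (1 degree of freedom).

    Sums observed minus expected group-1 events over the pooled distinct
    event times, with the hypergeometric variance; p from the chi-square
    upper tail.  Degenerate inputs with zero variance (e.g. no events)
    return chi-square 0, p 1.
    """
    times, events = _check_surv(times, events)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise DomainError(f"logrank_test requires exactly two groups, got {len(labels)}")
    g1 = group == labels[1]

    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        nj = at_risk.sum()
        n1j = (at_risk & g1).sum()
        dying = (times == t) & (events == 1)
        dj = dying.sum()
        d1j = (dying & g1).sum()
        o_minus_e += d1j - dj * n1j / nj
        if nj > 1:
            var += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    if var <= 0:
        return LogrankResult(0.0, 1.0)
    chi2 = o_minus_e ** 2 / var
    return LogrankResult(float(chi2), float(stats.chi2.sf(chi2, df=1)))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Result of a Cox partial-likelihood fit."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    log_partial_likelihood: float
    converged: bool
    ties_method: str
    n_iter: int = 0
    #: score (Rao) chi-square at β = 0, df = number of covariates
    score_chi2: float = float("nan")
    note: str = ""


def _cox_loglik(beta, t_sorted, e_sorted, X_sorted, ties, want_derivs=True):
    """Log partial likelihood (+ gradient, information) on presorted data.

    Data are sorted by *descending* time so prefix sums give risk-set sums.
    """
    n, p = X_sorted.shape
    eta = X_sorted @ beta
    eta = eta - eta.max()  # guard exp overflow; PL invariant to this shift
    w = np.exp(eta)
    wx = X_sorted * w[:, None]
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(wx, axis=0)
    if want_derivs:
        wxx = np.einsum("ij,ik->ijk", X_sorted, wx)
        cum_wxx = np.cumsum(wxx, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    # tie groups over descending times
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        last = j  # inclusive end of this time's block; risk set = rows 0..last
        ev = np.nonzero(e_sorted[i:last + 1])[0] + i
        d = len(ev)
        if d > 0:
            S0 = cum_w[last]
            S1 = cum_wx[last]
            s0d = w[ev].sum()
            s1d = wx[ev].sum(axis=0)
            ll += eta[ev].sum()
            if want_derivs:
                S2 = cum_wxx[last]
                s2d = wxx[ev].sum(axis=0)
                grad += X_sorted[ev].sum(axis=0)
            for el in range(d):
                frac = el / d if ties == "efron" else 0.0
                phi = S0 - frac * s0d
                ll -= np.log(phi)
                if want_derivs:
                    m = (S1 - frac * s1d) / phi
                    grad -= m
                    info += (S2 - frac * s2d) / phi - np.outer(m, m)
        i = last + 1
    return (ll, grad, info) if want_derivs else ll


def cox_log_partial_likelihood(beta, times, events, covariates,
                               ties: str = "breslow") -> float:
    """Log partial likelihood at a fixed coefficient vector (no fitting)."""
    times, events = _check_surv(times, events)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    order = np.argsort(-times, kind="stable")
    return float(_cox_loglik(np.asarray(beta, dtype=float), times[order],
                             events[order], X[order], ties, want_derivs=False))


def cox_fit(times, events, covariates, ties: str = "efron",
            max_iter: int = 50, tol: float = 1e-8) -> CoxFit:
    """Newton–Raphson Cox regression with step-halving.

    Convergence is declared when the largest component of the Newton step
    (score scaled by the information) falls below ``tol``.  Step-halving
    keeps the partial likelihood non-decreasing across iterations.  Monotone
    likelihoods (perfect separation, no events, constant covariates) are
    flagged ``converged=False`` rather than raised.
    """
    if ties not in ("efron", "breslow"):
        raise DomainError(f"unknown ties method {ties!r}")
    times, events = _check_surv(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != len(times):
        raise DomainError("covariate rows must match number of subjects")
    nan = np.full(p, np.nan)

    def degenerate(note):
        return CoxFit(np.zeros(p), nan, np.ones(p), nan, nan, nan,
                      log_partial_likelihood=float("nan"), converged=False,
                      ties_method=ties, score_chi2=float("nan"), note=note)

    if events.sum() == 0:
        return degenerate("no events: partial likelihood carries no information")
    if n <= p:
        return degenerate(f"n={n} too small for {p} covariates")
    const = np.all(X == X[0], axis=0)
    if const.any():
        return degenerate("constant covariate(s): " +
                          ", ".join(str(i) for i in np.nonzero(const)[0]))

    order = np.argsort(-times, kind="stable")
    ts, es, Xs = times[order], events[order], X[order]

    beta = np.zeros(p)
    ll, grad, info = _cox_loglik(beta, ts, es, Xs, ties)
    # score test at beta = 0
    try:
        score_chi2 = float(grad @ np.linalg.solve(info, grad))
    except np.linalg.LinAlgError:
        score_chi2 = float("nan")

    converged = False
    note = ""
    n_iter = 0
    singular = False
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
            singular = True
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        new_beta = beta + step
        new = _cox_loglik(new_beta, ts, es, Xs, ties)
        halvings = 0
        while new[0] < ll - 1e-12 and halvings < 30:
            step = step / 2
            new_beta = beta + step
            new = _cox_loglik(new_beta, ts, es, Xs, ties)
            halvings += 1
        beta, (ll, grad, info) = new_beta, new
        if np.max(np.abs(beta)) > 50:
            note = "monotone likelihood suspected (diverging coefficients)"
            break
    if singular:
        converged = False
        note = note or "singular information matrix (collinear covariates?)"

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
        note = note or "information matrix not invertible at the optimum"
    z2 = (beta / se) ** 2
    return CoxFit(
        coefficients=beta,
        standard_errors=se,
        hazard_ratios=np.exp(beta),
        ci_lower=np.exp(beta - _Z95 * se),
        ci_upper=np.exp(beta + _Z95 * se),
        p_values=stats.chi2.sf(z2, df=1),
        log_partial_likelihood=float(ll),
        converged=converged,
        ties_method=ties,
        n_iter=n_iter,
        score_chi2=score_chi2,
        note=note,
    )


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------

@dataclass
class TdROC:
    """Cumulative/dynamic time-dependent ROC at a fixed horizon.

    Cases are subjects with an observed event at or before the horizon;
    controls are subjects still under observation beyond it.  Both sides are
    reweighted by the inverse Kaplan–Meier estimate of the censoring
    distribution (IPCW).  ``thresholds`` are midpoints between adjacent
    observed marker values (plus sentinels outside the range), listed in
    decreasing order, and classify a sample positive when marker > threshold
    — the same strict rule used for risk-group assignment downstream.
    """

    horizon: float
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    marker_median: float
    n_cases: int
    n_controls: int
    variant: str = "ipcw-cumulative-dynamic"


def td_roc(times, events, marker, horizon: float) -> TdROC:
    """Time-dependent ROC (cumulative cases / dynamic controls) with IPCW."""
    times, events = _check_surv(times, events)
    marker = np.asarray(marker, dtype=float)
    if marker.shape != times.shape:
        raise DomainError("marker must have one value per subject")
    if not np.isfinite(marker).all():
        raise DomainError("marker values must be finite")
    if horizon <= 0:
        raise DomainError(f"horizon must be > 0, got {horizon}")

    is_case = (times <= horizon) & (events == 1)
    is_control = times > horizon
    if is_case.sum() == 0 or is_control.sum() == 0:
        raise DomainError(
            f"time-dependent ROC undefined at horizon {horizon}: "
            f"{int(is_case.sum())} case(s), {int(is_control.sum())} control(s)")

    cens_km = km_estimate(times, 1 - events)
    w = np.zeros(len(times))
    g_horizon = max(cens_km.survival_at(horizon), 1e-12)
    for i in np.nonzero(is_case)[0]:
        w[i] = 1.0 / max(cens_km.survival_at(times[i], left=True), 1e-12)
    w[is_control] = 1.0 / g_horizon

    uniq = np.unique(marker)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[-1] + 1.0], mids[::-1], [uniq[0] - 1.0]))

    w_case, w_ctrl = w[is_case], w[is_control]
    m_case, m_ctrl = marker[is_case], marker[is_control]
    tpr = np.array([w_case[m_case > c].sum() for c in thresholds]) / w_case.sum()
    fpr = np.array([w_ctrl[m_ctrl > c].sum() for c in thresholds]) / w_ctrl.sum()
    auc = float(np.trapezoid(tpr, fpr))
    return TdROC(horizon=float(horizon), thresholds=thresholds, tpr=tpr, fpr=fpr,
                 auc=auc, marker_median=float(np.median(marker)),
                 n_cases=int(is_case.sum()), n_controls=int(is_control.sum()))


def optimal_cutoff(roc: TdROC) -> float:
    """Threshold maximizing Youden's J = TPR − FPR.

    Ties (within 1e-12 of the maximum) are broken toward the threshold
    closest to the marker median, so a J = 1 plateau on a perfectly
    separating marker yields an interior cutoff.
    """
    j = roc.tpr - roc.fpr
    best = np.nonzero(j >= j.max() - 1e-12)[0]
    cand = roc.thresholds[best]
    return float(cand[np.argmin(np.abs(cand - roc.marker_median))])
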