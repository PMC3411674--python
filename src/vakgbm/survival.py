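"""Kaplan-Meier estimation, log-rank testing and Cox proportional-hazards fitting.

All three are implemented directly from the defining formulas (product-limit
estimator; two-group log-rank with hypergeometric variance; Newton-Raphson
maximization of the Cox partial likelihood with Efron or Breslow tie handling)
so that they can be checked against hand computations and brute-force oracles.

Tie convention: events precede censorings at the same time, i.e. a subject
censored at t is still in the risk set for events at t — the convention used by
mainstream survival software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConvergenceError


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) evaluated at the distinct event times."""

    event_times: np.ndarray      # increasing distinct event times
    survival_probs: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray          # n_i at risk just before each event time
    n_events: np.ndarray         # d_i events at each event time
    n: int                       # cohort size

    def survival_at(self, t: float) -> float:
        """S(t); 1.0 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


@dataclass
class LogRankResult:
    chi2: float
    p: float
    observed: tuple[float, float]   # events in group A, group B
    expected: tuple[float, float]


@dataclass
class CoxFit:
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    lr_stat: float
    lr_p: float
    n_iter: int
    ties: str


def _check_times(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return times, events


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod (1 - d_i/n_i)."""
    times, events = _check_times(times, events)
    n = times.size
    event_times = np.unique(times[events == 1])
    probs = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n_i = int((times >= t).sum())
        d_i = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_i / n_i
        probs[i] = s
        at_risk[i] = n_i
        d[i] = d_i
    return SurvivalCurve(event_times, probs, at_risk, d, n)


def km_median(curve: SurvivalCurve) -> float | None:
    """Smallest event time t with S(t) <= 0.5; None ("not reached") otherwise."""
    below = np.nonzero(curve.survival_probs <= 0.5)[0]
    if below.size == 0:
        return None
    return float(curve.event_times[below[0]])


def logrank(timesA, eventsA, timesB, eventsB) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time the observed events in group A are compared
    with the hypergeometric expectation given the pooled risk set; the
    statistic (sum O - sum E)^2 / sum V is referred to chi-square with 1 df.
    """
    timesA, eventsA = _check_times(timesA, eventsA)
    timesB, eventsB = _check_times(timesB, eventsB)
    if eventsA.sum() + eventsB.sum() == 0:
        raise ValueError("no events in either group")
    times = np.concatenate([timesA, timesB])
    events = np.concatenate([eventsA, eventsB])
    group = np.concatenate([np.zeros(timesA.size, dtype=int), np.ones(timesB.size, dtype=int)])
    o_a = e_a = v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_t = int(at_risk.sum())
        n_a = int((at_risk & (group == 0)).sum())
        died = (times == t) & (events == 1)
        d_t = int(died.sum())
        d_a = int((died & (group == 0)).sum())
        o_a += d_a
        e_a += d_t * n_a / n_t
        if n_t > 1:
            v += d_t * (n_a / n_t) * (1 - n_a / n_t) * (n_t - d_t) / (n_t - 1)
    total_events = float(eventsA.sum() + eventsB.sum())
    if v == 0.0:
        chi2 = 0.0
    else:
        chi2 = (o_a - e_a) ** 2 / v
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return LogRankResult(
        chi2=float(chi2),
        p=p,
        observed=(o_a, total_events - o_a),
        expected=(e_a, total_events - e_a),
    )


def _cox_ll_grad_hess(
    beta: np.ndarray,
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ties: str,
):
    """Partial log-likelihood, gradient and Hessian at beta."""
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for t in np.unique(times[events == 1]):
        risk = times >= t
        died = (times == t) & (events == 1)
        d = int(died.sum())
        s_r = w[risk].sum()
        xs_r = X[risk].T @ w[risk]
        xx_r = (X[risk] * w[risk, None]).T @ X[risk]
        s_d = w[died].sum()
        xs_d = X[died].T @ w[died]
        xx_d = (X[died] * w[died, None]).T @ X[died]
        ll += eta[died].sum()
        n_terms = d if ties == "efron" else 1
        for l in range(n_terms):
            frac = l / d if ties == "efron" else 0.0
            denom = s_r - frac * s_d
            z = xs_r - frac * xs_d
            zz = xx_r - frac * xx_d
            if ties == "breslow":
                ll -= d * np.log(denom)
                grad_term = d * z / denom
                hess_term = d * (zz / denom - np.outer(z, z) / denom**2)
            else:
                ll -= np.log(denom)
                grad_term = z / denom
                hess_term = zz / denom - np.outer(z, z) / denom**2
            grad -= grad_term
            hess += hess_term
    grad += X[events == 1].sum(axis=0)
    return ll, grad, hess  # hess is the observed information (negated Hessian), PSD


def cox_fit(
    covariates,
    times,
    events,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Returns coefficients, hazard ratios exp(beta), the maximized partial
    log-likelihood and the likelihood-ratio test against the null model
    (all coefficients zero). Step-halving is used if a Newton step decreases
    the likelihood; a coefficient escaping to +/-inf (monotone likelihood,
    i.e. separation) raises :class:`ConvergenceError` naming the covariate.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times, events = _check_times(times, events)
    n, p = X.shape
    if events.sum() == 0:
        raise ValueError("no events; Cox model undefined")
    # center covariates for numerical stability (does not change beta)
    X = X - X.mean(axis=0)
    scale = X.std(axis=0)  # detect separation on the standardized scale
    scale[scale == 0] = 1.0

    beta = np.zeros(p)
    ll_null, _, _ = _cox_ll_grad_hess(beta, X, times, events, ties)
    ll_old = ll_null
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, grad, hess = _cox_ll_grad_hess(beta, X, times, events, ties)
        if np.allclose(hess, 0):
            break  # no information (constant covariates)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halving line search
        new_beta = beta + step
        ll_new, _, _ = _cox_ll_grad_hess(new_beta, X, times, events, ties)
        halvings = 0
        while ll_new < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            ll_new, _, _ = _cox_ll_grad_hess(new_beta, X, times, events, ties)
            halvings += 1
        beta = new_beta
        if (np.abs(beta) * scale).max() > 20:
            j = int((np.abs(beta) * scale).argmax())
            raise ConvergenceError(
                f"monotone partial likelihood (separation) for covariate {j}"
            )
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + tol):
            ll_old = ll_new
            break
        ll_old = ll_new
    else:
        j = int((np.abs(beta) * scale).argmax())
        if (np.abs(beta) * scale)[j] > 5:
            raise ConvergenceError(
                f"monotone partial likelihood (separation) for covariate {j}"
            )
        raise ConvergenceError(f"Cox fit did not converge in {max_iter} iterations")

    ll_final, _, hess = _cox_ll_grad_hess(beta, X, times, events, ties)
    if np.allclose(hess, 0):
        se = np.full(p, np.inf)
    else:
        se = np.sqrt(np.diag(np.linalg.inv(hess)))
    lr = max(0.0, 2.0 * (ll_final - ll_null))
    lr_p = float(stats.chi2.sf(lr, df=p)) if lr > 0 else 1.0
    return CoxFit(
        coefficients=beta,
        hazard_ratios=np.exp(beta),
        standard_errors=se,
        log_likelihood=float(ll_final),
        null_log_likelihood=float(ll_null),
        lr_stat=float(lr),
        lr_p=lr_p,
        n_iter=n_iter,
        ties=ties,
    )


def lr_compare(full: CoxFit, reduced: CoxFit, df: int) -> tuple[float, float]:
    """Likelihood-ratio comparison of nested Cox fits (full vs reduced)."""
    stat = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = float(stats.chi2.sf(stat, df=df)) if stat > 0 else 1.0
    return stat, p
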