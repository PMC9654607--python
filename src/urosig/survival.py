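"""Survival analysis: Kaplan–Meier, two-group tests, hazard ratios, Cox.

Implements the product-limit estimator, the Mantel-Cox (log-rank) and
Gehan–Breslow–Wilcoxon two-group tests built from per-event-time 2x2
tables, hazard-ratio estimates in both the Mantel-Haenszel
exp((O-E)/V) and observed/expected-ratio forms, and single-covariate
Cox proportional-hazards regression maximising the partial likelihood
by Newton–Raphson with the Efron tie correction (Breslow available).

Conventions: individuals censored exactly at an event time are
counted at risk at that time; all p-values are two-sided, with the
chi-square(1) reference for the two-group tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import ClinicalTable

__all__ = [
    "KMCurve",
    "TwoGroupTest",
    "HazardRatioEstimate",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "gehan_breslow_wilcoxon",
    "hazard_ratio",
    "cox_ph",
    "cox_score_test",
]


@dataclass
class KMCurve:
    """Product-limit survival curve over the distinct event times."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t): survival just after time t."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class TwoGroupTest:
    method: str
    chi_square: float
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]
    variance_sum: float


@dataclass
class HazardRatioEstimate:
    method: str
    hr: float
    ci95: tuple[float, float]


@dataclass
class CoxFit:
    beta: float
    se: float
    hr: float
    wald_p: float
    ci95: tuple[float, float]
    iterations: int
    converged: bool
    loglik: float = float("nan")
    flag: str = ""


def _arrays(records: ClinicalTable) -> tuple[np.ndarray, np.ndarray]:
    return records.time, records.event


def km_estimate(records: ClinicalTable) -> KMCurve:
    """Kaplan–Meier product-limit estimate S(t) = prod (1 - d_j/n_j)."""
    if len(records) == 0:
        raise ValueError("no records")
    time, event = _arrays(records)
    event_times = np.unique(time[event == 1])
    n_at_risk = np.array([(time >= t).sum() for t in event_times], int)
    n_events = np.array(
        [((time == t) & (event == 1)).sum() for t in event_times], int)
    if event_times.size == 0:
        return KMCurve(event_times, n_at_risk, n_events,
                       np.ones(0))
    surv = np.cumprod(1.0 - n_events / n_at_risk)
    return KMCurve(event_times, n_at_risk, n_events, surv)


def _event_tables(a: ClinicalTable, b: ClinicalTable):
    """Per-event-time 2x2 table quantities for two-group tests.

    Returns arrays over the pooled distinct event times:
    n (total at risk), n_a, d (total events), d_a, plus the group-a
    expectation E_a = n_a d / n and the hypergeometric variance
    V = n_a n_b d (n-d) / (n^2 (n-1)).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ta, ea = _arrays(a)
    tb, eb = _arrays(b)
    times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    if times.size == 0:
        raise ValueError("no events in either group")
    n_a = np.array([(ta >= t).sum() for t in times], float)
    n_b = np.array([(tb >= t).sum() for t in times], float)
    d_a = np.array([((ta == t) & (ea == 1)).sum() for t in times], float)
    d_b = np.array([((tb == t) & (eb == 1)).sum() for t in times], float)
    n = n_a + n_b
    d = d_a + d_b
    e_a = n_a * d / n
    with np.errstate(invalid="ignore", divide="ignore"):
        v = n_a * n_b * d * (n - d) / (n ** 2 * (n - 1.0))
    v[n <= 1] = 0.0
    return times, n, n_a, d, d_a, e_a, v


def _two_group(a: ClinicalTable, b: ClinicalTable, weights: str) -> TwoGroupTest:
    times, n, n_a, d, d_a, e_a, v = _event_tables(a, b)
    w = n if weights == "gehan" else np.ones_like(n)
    denom = float((w ** 2 * v).sum())
    if denom <= 0:
        raise ValueError(
            "zero total variance: every event-time table is degenerate "
            "(e.g. all at-risk individuals fail together)")
    num = float((w * (d_a - e_a)).sum())
    chi = num ** 2 / denom
    p = float(stats.chi2.sf(chi, 1))
    method = "gehan_breslow_wilcoxon" if weights == "gehan" else "mantel_cox"
    return TwoGroupTest(
        method, chi, p,
        observed={"a": float(d_a.sum()), "b": float((d - d_a).sum())},
        expected={"a": float(e_a.sum()), "b": float((d - e_a).sum())},
        variance_sum=float(v.sum()),
    )


def logrank_test(a: ClinicalTable, b: ClinicalTable) -> TwoGroupTest:
    """Mantel-Cox (log-rank) test: chi^2 = (sum O_a - sum E_a)^2 / sum V."""
    return _two_group(a, b, weights="logrank")


def gehan_breslow_wilcoxon(a: ClinicalTable, b: ClinicalTable) -> TwoGroupTest:
    """Gehan–Breslow–Wilcoxon test: event times weighted by total at risk,
    emphasising early differences between the curves."""
    return _two_group(a, b, weights="gehan")


def hazard_ratio(
    a: ClinicalTable, b: ClinicalTable, method: str = "mantel_haenszel"
) -> HazardRatioEstimate:
    """Hazard ratio of group a relative to group b.

    mantel_haenszel: exp((O_a - E_a) / sum V);
    logrank_oe: (O_a/E_a) / (O_b/E_b).
    Both use the CI form hr * exp(+-1.96 / sqrt(sum V)).
    """
    if a.event.sum() < 1 or b.event.sum() < 1:
        raise ValueError("both groups need at least one event")
    times, n, n_a, d, d_a, e_a, v = _event_tables(a, b)
    o_a, o_b = float(d_a.sum()), float((d - d_a).sum())
    e_a_sum, e_b_sum = float(e_a.sum()), float((d - e_a).sum())
    v_sum = float(v.sum())
    if v_sum <= 0:
        raise ValueError("zero total variance")
    if method == "mantel_haenszel":
        log_hr = (o_a - e_a_sum) / v_sum
        hr = math.exp(log_hr)
    elif method == "logrank_oe":
        if o_b == 0 or e_b_sum == 0:
            raise ValueError("O/E ratio undefined: group b has O or E of 0")
        if o_a == 0 or e_a_sum == 0:
            raise ValueError("O/E ratio undefined: group a has O or E of 0")
        hr = (o_a / e_a_sum) / (o_b / e_b_sum)
        log_hr = math.log(hr)
    else:
        raise ValueError(f"unknown method {method!r}")
    half = 1.96 / math.sqrt(v_sum)
    return HazardRatioEstimate(
        method, hr, (math.exp(log_hr - half), math.exp(log_hr + half)))


# ---------------------------------------------------------------------------
# Cox proportional hazards (single covariate)


def _cox_derivatives(beta: float, time: np.ndarray, event: np.ndarray,
                     x: np.ndarray, ties: str):
    """(loglik, gradient, information) of the partial likelihood."""
    order = np.argsort(time, kind="mergesort")
    t, e, xv = time[order], event[order], x[order]
    eta = beta * xv
    w = np.exp(eta)
    # suffix sums over the risk set {i : t_i >= t}
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * xv)[::-1])[::-1]
    s2 = np.cumsum((w * xv * xv)[::-1])[::-1]

    loglik = grad = info = 0.0
    event_times = np.unique(t[e == 1])
    for et in event_times:
        first = np.searchsorted(t, et, side="left")
        dead = (t == et) & (e == 1)
        d = int(dead.sum())
        xd = xv[dead]
        wd = w[dead]
        s0r, s1r, s2r = s0[first], s1[first], s2[first]
        if ties == "breslow" or d == 1:
            loglik += float(beta * xd.sum() - d * math.log(s0r))
            grad += float(xd.sum() - d * s1r / s0r)
            info += float(d * (s2r / s0r - (s1r / s0r) ** 2))
        elif ties == "efron":
            frac = np.arange(d) / d
            s0l = s0r - frac * wd.sum()
            s1l = s1r - frac * (wd * xd).sum()
            s2l = s2r - frac * (wd * xd * xd).sum()
            loglik += float(beta * xd.sum() - np.log(s0l).sum())
            grad += float(xd.sum() - (s1l / s0l).sum())
            info += float((s2l / s0l - (s1l / s0l) ** 2).sum())
        else:
            raise ValueError(f"unknown tie method {ties!r}")
    return loglik, grad, info


def cox_ph(
    records: ClinicalTable,
    covariate: np.ndarray,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Single-covariate Cox regression by Newton–Raphson from beta = 0.

    The Efron approximation handles tied event times (Breslow is
    available and agrees exactly when no ties occur).  Convergence is
    a gradient below ``tol``; a runaway beta (monotone likelihood /
    perfect separation) is flagged rather than raising.
    """
    time, event = _arrays(records)
    x = np.asarray(covariate, float)
    if x.shape != time.shape:
        raise ValueError("covariate must align with the clinical records")
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate is unidentifiable")

    beta, it, flag = 0.0, 0, ""
    converged = False
    loglik = grad = info = float("nan")
    for it in range(1, max_iter + 1):
        loglik, grad, info = _cox_derivatives(beta, time, event, x, ties)
        if abs(grad) < tol:
            converged = True
            break
        if info <= 0:
            flag = "singular information"
            break
        step = grad / info
        beta += step
        if abs(beta) > 20:
            flag = "monotone likelihood (possible perfect separation)"
            break
    if converged:
        loglik, grad, info = _cox_derivatives(beta, time, event, x, ties)
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    z = beta / se if se > 0 and math.isfinite(se) else float("nan")
    wald_p = float(2.0 * stats.norm.sf(abs(z))) if math.isfinite(z) else float("nan")
    ci = (beta - 1.96 * se, beta + 1.96 * se)
    return CoxFit(beta=float(beta), se=float(se), hr=float(math.exp(beta)),
                  wald_p=wald_p, ci95=(math.exp(ci[0]), math.exp(ci[1])),
                  iterations=it, converged=converged, loglik=float(loglik),
                  flag=flag)


def cox_score_test(records: ClinicalTable, covariate: np.ndarray,
                   ties: str = "efron") -> tuple[float, float]:
    """Score (log-rank-type) test of beta = 0: U(0)^2 / I(0).

    With a binary covariate and no tied event times this equals the
    Mantel-Cox chi-square exactly.
    """
    time, event = _arrays(records)
    x = np.asarray(covariate, float)
    _, grad, info = _cox_derivatives(0.0, time, event, x, ties)
    if info <= 0:
        raise ValueError("zero information at beta=0")
    chi = grad ** 2 / info
    return float(chi), float(stats.chi2.sf(chi, 1))
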