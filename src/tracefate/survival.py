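"""Median-split prognosis analysis and hazard-ratio meta-analysis.

Per cohort, patients are split at the cohort-median expression (ties go to
the low stratum), survival is summarised by the Kaplan-Meier product-limit
estimator, and the low-vs-high hazard ratio is estimated by maximising the
Cox partial likelihood for the single binary stratum covariate with
Newton's method, handling tied event times with Efron's approximation.
Per-cohort log hazard ratios and their standard errors are then combined
by fixed-effect inverse-variance weighting (DerSimonian-Laird
random-effects available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import (
    DegenerateStratificationError,
    InvalidParameterError,
    NoInformationError,
)

# ---------------------------------------------------------------------------
# Stratification and Kaplan-Meier
# ---------------------------------------------------------------------------


def median_split(expressions) -> np.ndarray:
    """Binary strata: True for high (strictly above median), False for low.

    Values equal to the median are assigned to the low stratum.
    """
    x = np.asarray(expressions, dtype=float)
    if x.size < 4:
        raise InvalidParameterError("need >= 4 patients to stratify")
    if np.all(x == x[0]):
        raise DegenerateStratificationError("all expression values identical")
    return x > np.median(x)


def km_curve(times, events):
    """Product-limit survival estimate.

    Returns (event_times, survival) where survival[i] is S(t) just after
    event_times[i]; S(0) = 1 and the curve is non-increasing.  Censored
    observations shrink the risk set without a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise InvalidParameterError("negative survival times")
    if times.size == 0:
        raise InvalidParameterError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return sf.index.to_numpy(), sf.iloc[:, 0].to_numpy()


# ---------------------------------------------------------------------------
# Cox partial likelihood, single binary covariate, Efron ties
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoxResult:
    """Low-vs-high hazard-ratio estimate for one cohort."""

    log_hr: float
    se: float
    hr: float
    wald_z: float
    p: float
    n_low: int
    n_high: int
    n_events: int
    monotone: bool = False  # complete separation; estimate bounded, se unreliable


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Efron-approximation log partial likelihood at a given beta.

    Exposed for brute-force oracle checks; x is the 0/1 covariate.
    """
    ll, _, _ = _efron_derivatives(beta, *_prepare(times, events, x))
    return ll


def _prepare(times, events, x):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    order = np.argsort(times, kind="stable")
    return times[order], events[order], x[order]


def _efron_derivatives(beta, times, events, x):
    """(loglik, gradient, hessian) of the Efron partial likelihood (sorted input)."""
    r = np.exp(beta * x)
    event_times = np.unique(times[events == 1])
    ll = grad = hess = 0.0
    for t in event_times:
        at_risk = times >= t
        tied = (times == t) & (events == 1)
        d = int(tied.sum())
        s0_r = r[at_risk].sum()
        s1_r = (x[at_risk] * r[at_risk]).sum()
        s2_r = (x[at_risk] ** 2 * r[at_risk]).sum()
        s0_d = r[tied].sum()
        s1_d = (x[tied] * r[tied]).sum()
        s2_d = (x[tied] ** 2 * r[tied]).sum()
        ll += beta * x[tied].sum()
        for l in range(d):
            f = l / d
            phi0 = s0_r - f * s0_d
            phi1 = s1_r - f * s1_d
            phi2 = s2_r - f * s2_d
            ll -= np.log(phi0)
            grad_term = phi1 / phi0
            grad += x[tied].sum() / d - grad_term  # spread numerator over the d terms
            hess -= phi2 / phi0 - grad_term**2
    return ll, grad, hess


def cox_fit_binary(times, events, group_low) -> CoxResult:
    """Newton maximisation of the Cox partial likelihood, low (x=1) vs high (x=0).

    A positive log HR means the low stratum has the higher hazard.  Tied
    event times use Efron's approximation; the standard error comes from
    the observed information.  Complete separation (all events in one
    group) yields a bounded estimate flagged ``monotone=True``.
    """
    times, events, x = _prepare(times, events, np.asarray(group_low, dtype=float))
    if events.sum() == 0:
        raise NoInformationError("no events in the pooled data")
    n_low = int(x.sum())
    n_high = int(x.size - n_low)
    if n_low == 0 or n_high == 0:
        raise InvalidParameterError("both strata must be non-empty")
    beta = 0.0
    monotone = False
    BOUND = 15.0
    for _ in range(50):
        ll, grad, hess = _efron_derivatives(beta, times, events, x)
        if hess >= 0 or not np.isfinite(hess):
            monotone = True
            break
        step = -grad / hess
        beta_new = float(np.clip(beta + step, -BOUND, BOUND))
        if abs(beta_new) >= BOUND:
            monotone = True
            beta = beta_new
            break
        if abs(beta_new - beta) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    _, _, hess = _efron_derivatives(beta, times, events, x)
    se = float(1.0 / np.sqrt(-hess)) if hess < 0 else float("inf")
    if monotone:
        warnings.warn("monotone partial likelihood (complete separation); "
                      "estimate bounded, standard error unreliable")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxResult(
        log_hr=float(beta), se=se, hr=float(np.exp(beta)), wald_z=float(z),
        p=float(p), n_low=n_low, n_high=n_high, n_events=int(events.sum()),
        monotone=monotone,
    )


def cox_by_median_split(times, events, expressions) -> CoxResult:
    """Convenience: median-split expression, then Cox low-vs-high."""
    high = median_split(expressions)
    return cox_fit_binary(times, events, ~high)


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance combined hazard ratio across cohorts."""

    combined_log_hr: float
    combined_se: float
    hr: float
    hr_ci95: tuple
    z: float
    p: float
    per_study: tuple
    model: str  # 'fixed' or 'random'
    tau2: float = 0.0


def meta_fixed(results: list[CoxResult], random_effects: bool = False) -> MetaResult:
    """Combine per-study log hazard ratios by inverse-variance weighting.

    Fixed effect: weights 1/se^2, combined se = (sum of weights)^(-1/2).
    ``random_effects=True`` applies the DerSimonian-Laird between-study
    variance tau^2 to the weights instead.
    """
    if not results:
        raise InvalidParameterError("need at least one study")
    if any(r.se <= 0 or not np.isfinite(r.se) for r in results):
        raise InvalidParameterError("all studies need a finite positive se")
    theta = np.array([r.log_hr for r in results])
    v = np.array([r.se**2 for r in results])
    w = 1.0 / v
    fixed_est = float((w * theta).sum() / w.sum())
    tau2 = 0.0
    if random_effects and len(results) > 1:
        q = float((w * (theta - fixed_est) ** 2).sum())
        c = float(w.sum() - (w**2).sum() / w.sum())
        tau2 = max(0.0, (q - (len(results) - 1)) / c) if c > 0 else 0.0
        w = 1.0 / (v + tau2)
    est = float((w * theta).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    ci = (float(np.exp(est - 1.96 * se)), float(np.exp(est + 1.96 * se)))
    return MetaResult(
        combined_log_hr=est, combined_se=se, hr=float(np.exp(est)), hr_ci95=ci,
        z=float(z), p=float(p), per_study=tuple(results),
        model="random" if random_effects else "fixed", tau2=tau2,
    )
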