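"""Survival and categorical statistics used throughout the pipeline.

Kaplan-Meier product-limit curves, the two-group log-rank test, Cox
proportional-hazards regression (Newton-Raphson partial likelihood with Efron
tie handling and step halving), median expression splits, Pearson chi-square
association and Benjamini-Hochberg FDR.

The Cox and log-rank machinery is implemented here directly: the score test
of the Cox model at beta = 0 for a binary covariate coincides with the
log-rank chi-square in the absence of ties, a relationship the test-suite
checks numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the event times."""

    times: np.ndarray          # ascending unique event times
    survival: np.ndarray       # S(t) just after each time, non-increasing
    at_risk: np.ndarray        # n at risk just before each time
    n_events: np.ndarray       # events at each time

    def survival_at(self, t: float) -> float:
        """Right-continuous step evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvivalFit:
    """One covariate row of a Cox proportional-hazards fit."""

    covariate: str
    coef: float
    hr: float
    log_hr_se: float
    ci95: tuple[float, float]
    p: float
    n: int
    n_events: int


@dataclass
class CoxResult:
    fits: list[SurvivalFit]
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    score_chi2: float = np.nan      # global score test at beta = 0
    score_df: int = 0
    score_p: float = np.nan

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "covariate": f.covariate, "coef": f.coef, "hr": f.hr,
                    "se": f.log_hr_se, "ci_low": f.ci95[0], "ci_high": f.ci95[1],
                    "p": f.p, "n": f.n, "n_events": f.n_events,
                }
                for f in self.fits
            ]
        )


def _check_times_events(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events length mismatch")
    if (times < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return times, events.astype(int)


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier estimate; events processed before censorings at ties."""
    times, events = _check_times_events(times, events)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        # censored-only input: flat curve at 1 over the observed times
        t = np.unique(times)
        return KMCurve(times=t, survival=np.ones_like(t),
                       at_risk=np.array([(times >= x).sum() for x in t]),
                       n_events=np.zeros_like(t, dtype=int))
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in event_times:
        n = int((times >= t).sum())        # ties: events counted in risk set
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n
        surv.append(s)
        at_risk.append(n)
        n_ev.append(d)
    return KMCurve(times=event_times, survival=np.array(surv),
                   at_risk=np.array(at_risk), n_events=np.array(n_ev))


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test (1 df, hypergeometric variance).

    Returns (chi2, p).  Times where only one subject remains at risk
    contribute zero variance.
    """
    times, events = _check_times_events(times, events)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"logrank_test needs exactly 2 groups, got {labels.size}")
    if events.sum() == 0:
        raise ValueError("no events")
    in_a = group == labels[0]
    o_a = e_a = v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = int(((times == t) & (events == 1)).sum())
        d_a = int(((times == t) & (events == 1) & in_a).sum())
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            v += d * (n - d) * n_a * (n - n_a) / (n**2 * (n - 1))
    if v == 0:
        return 0.0, 1.0
    chi2 = (o_a - e_a) ** 2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def multigroup_logrank(times, events, group) -> tuple[float, int, float]:
    """k-group log-rank test (k-1 df) via per-group O-E sums and covariance."""
    times, events = _check_times_events(times, events)
    group = np.asarray(group)
    labels = np.unique(group)
    k = labels.size
    if k < 2:
        raise ValueError("need >= 2 groups")
    oe = np.zeros(k)
    cov = np.zeros((k, k))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        d = int(((times == t) & (events == 1)).sum())
        ng = np.array([(at_risk & (group == g)).sum() for g in labels], dtype=float)
        dg = np.array([((times == t) & (events == 1) & (group == g)).sum()
                       for g in labels], dtype=float)
        oe += dg - d * ng / n
        if n > 1:
            f = d * (n - d) / (n - 1)
            p = ng / n
            cov += f * (np.diag(p) - np.outer(p, p))
    sub = slice(0, k - 1)
    chi2 = float(oe[sub] @ np.linalg.solve(cov[sub, sub], oe[sub]))
    return chi2, k - 1, float(stats.chi2.sf(chi2, df=k - 1))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)


def _cox_loglik_derivs(beta, x, times, events, ties="efron"):
    """Partial log-likelihood, gradient and Hessian (negative curvature)."""
    n, p = x.shape
    eta = x @ beta
    eta -= eta.max()  # guard exp overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # descending time: prefix = risk set
    xs, ts, es, ws, etas = x[order], times[order], events[order], w[order], eta[order]
    s0 = np.cumsum(ws)
    s1 = np.cumsum(ws[:, None] * xs, axis=0)
    s2 = np.cumsum(ws[:, None, None] * (xs[:, :, None] * xs[:, None, :]), axis=0)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        die = np.arange(i, j)[es[i:j] == 1]
        d = die.size
        if d:
            r0 = s0[j - 1]
            r1 = s1[j - 1]
            r2 = s2[j - 1]
            wd = ws[die]
            d0 = wd.sum()
            d1 = (wd[:, None] * xs[die]).sum(axis=0)
            d2 = (wd[:, None, None] * (xs[die][:, :, None] * xs[die][:, None, :])).sum(axis=0)
            ll += etas[die].sum()
            grad += xs[die].sum(axis=0)
            if ties == "efron":
                fracs = np.arange(d) / d
            else:  # breslow
                fracs = np.zeros(d)
            for frac in fracs:
                a0 = r0 - frac * d0
                a1 = r1 - frac * d1
                a2 = r2 - frac * d2
                ll -= np.log(a0)
                grad -= a1 / a0
                hess -= a2 / a0 - np.outer(a1, a1) / a0**2
        i = j
    return ll, grad, hess


def cox_ph(
    covariates: pd.DataFrame | np.ndarray,
    times,
    events,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-6,
) -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson with step halving.

    ``covariates`` is an n-by-p matrix (DataFrame columns become covariate
    names); ordinal covariates such as stage/grade enter as integers.  Raises
    on constant covariates, zero events, or non-convergence.
    """
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(covariates, dtype=float))
        if x.shape[0] == 1 and x.size > 1:
            x = x.T
        names = [f"x{i}" for i in range(x.shape[1])]
    times, events = _check_times_events(times, events)
    if x.shape[0] != times.size:
        raise ValueError("covariate rows must match number of samples")
    if events.sum() == 0:
        raise ValueError("no events")
    sds = x.std(axis=0)
    if (sds == 0).any():
        bad = names[int(np.argmin(sds))]
        raise ValueError(f"constant covariate {bad!r}")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")

    p = x.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik_derivs(beta, x, times, events, ties)
    # global score test at beta = 0
    info0 = -hess
    try:
        score_chi2 = float(grad @ np.linalg.solve(info0, grad))
        score_p = float(stats.chi2.sf(score_chi2, df=p))
    except np.linalg.LinAlgError:
        score_chi2, score_p = np.nan, np.nan
    trace = [ll]
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as e:
            raise ValueError(f"singular information matrix: {e}") from None
        # step halving keeps the partial likelihood monotone
        t = 1.0
        for _ in range(30):
            new_beta = beta + t * step
            new_ll, new_grad, new_hess = _cox_loglik_derivs(
                new_beta, x, times, events, ties)
            if new_ll >= ll - 1e-12:
                break
            t /= 2.0
        improved = new_ll - ll
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        trace.append(ll)
        if np.abs(grad).max() < tol or improved < 1e-12 * max(abs(ll), 1.0):
            break
    else:
        raise ValueError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(last gradient norm {np.abs(grad).max():.3g})"
        )
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    fits = [
        SurvivalFit(
            covariate=names[i],
            coef=float(beta[i]),
            hr=float(np.exp(beta[i])),
            log_hr_se=float(se[i]),
            ci95=(float(np.exp(beta[i] - 1.959963984540054 * se[i])),
                  float(np.exp(beta[i] + 1.959963984540054 * se[i]))),
            p=float(pvals[i]),
            n=int(times.size),
            n_events=int(events.sum()),
        )
        for i in range(p)
    ]
    return CoxResult(fits=fits, loglik=float(ll), loglik_trace=trace,
                     score_chi2=score_chi2, score_df=p, score_p=score_p)


# ---------------------------------------------------------------------------
# simple helpers


def median_split(values) -> np.ndarray:
    """Split at the median: value > median -> "high", <= median -> "low"."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("median_split needs n >= 2")
    med = np.median(values)
    labels = np.where(values > med, "high", "low")
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate split: all values on one side of the median")
    return labels


def categorical_association(labels_a, labels_b) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-square test of independence (no continuity correction).

    Returns (chi2, df, p, expected-counts table).
    """
    table = pd.crosstab(pd.Series(labels_a), pd.Series(labels_b))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table (needs >= 2 rows and columns)")
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    exp_df = pd.DataFrame(expected, index=table.index, columns=table.columns)
    return float(chi2), int(dof), float(p), exp_df


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
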