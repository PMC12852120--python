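"""Survival machinery: Kaplan-Meier estimation, log-rank testing, Cox
proportional-hazards regression, and the cohort-construction filters used
for hotspot-group comparisons.

KM curves and log-rank tests wrap lifelines; the Cox model is a direct
Newton maximization of the Breslow partial likelihood (gradient norm
< 1e-8 or a declared non-convergence), which keeps the classical
equivalence between the single-binary-covariate score test and the
two-group log-rank statistic exact on tie-free data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

PREINVASIVE_STAGES = {"AAH", "AIS", "MIA"}
STAGE_I = {"I", "IA", "IB"}


@dataclass
class KmCurve:
    times: np.ndarray  # distinct event times
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) at each event time
    variance: np.ndarray  # Greenwood variance of S(t)


@dataclass
class CoxFit:
    coef: pd.Series  # log hazard ratios
    se: pd.Series
    p_values: pd.Series
    log_likelihood: float
    converged: bool
    n_iter: int
    separation_flag: bool = False


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KmCurve:
    """Product-limit estimator with Greenwood variance.

    Subjects censored exactly at an event time count in the at-risk set at
    that time (the standard convention).  With no events, S(t) = 1
    throughout (empty curve arrays).
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if (t <= 0).any():
        raise ValueError("times must be positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("event flags must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    n = ev["at_risk"].to_numpy(float)
    d = ev["observed"].to_numpy(float)
    surv = np.cumprod(1.0 - d / n)
    # Greenwood terms; where n == d the curve reaches 0 and its variance is 0
    terms = np.where(n > d, d / (n * np.maximum(n - d, 1)), 0.0)
    var = surv**2 * np.cumsum(terms)
    return KmCurve(
        times=ev.index.to_numpy(float),
        at_risk=n,
        n_events=d,
        survival=surv,
        variance=var,
    )


def km_survival_at(curve: KmCurve, t: float) -> float:
    """S(t) from a fitted curve (right-continuous step function)."""
    if len(curve.times) == 0 or t < curve.times[0]:
        return 1.0
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return float(curve.survival[idx])


def km_median(times: Sequence[float], events: Sequence[int]) -> float:
    """Smallest event time with S(t) <= 0.5 (inf when never reached)."""
    curve = km_estimate(times, events)
    below = np.flatnonzero(curve.survival <= 0.5)
    return float(curve.times[below[0]]) if len(below) else float("inf")


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> tuple[float, int, float]:
    """K-group log-rank test; returns (chi-square statistic, df, p)."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = pd.Series(groups)
    labels = g.unique()
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    counts = g.value_counts()
    if (counts < 1).any():
        raise ValueError("every group needs >= 1 subject")
    res = multivariate_logrank_test(t, g.to_numpy(), e)
    df = len(labels) - 1
    return float(res.test_statistic), df, float(res.p_value)


def _cox_quantities(beta: np.ndarray, x: np.ndarray, t: np.ndarray, e: np.ndarray):
    """Breslow partial log-likelihood, gradient and Hessian.

    Samples are sorted by descending time so every risk set is a prefix of
    the sorted arrays; tied event times share the same (full) risk set.
    """
    order = np.argsort(-t, kind="stable")
    xs, ts, es = x[order], t[order], e[order]
    eta = xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * xs, axis=0)
    s2 = np.cumsum(w[:, None, None] * (xs[:, :, None] * xs[:, None, :]), axis=0)
    ll, grad = 0.0, np.zeros(len(beta))
    hess = np.zeros((len(beta), len(beta)))
    ev_idx = np.flatnonzero(es == 1)
    for i in ev_idx:
        # risk set: all with time >= ts[i]; with descending sort that is the
        # prefix up to the last position sharing ts[i]
        m = np.searchsorted(-ts, -ts[i], side="right") - 1
        ll += eta[i] - np.log(s0[m])
        mu = s1[m] / s0[m]
        grad += xs[i] - mu
        hess -= s2[m] / s0[m] - np.outer(mu, mu)
    return ll, grad, hess


def cox_fit(
    times: Sequence[float],
    events: Sequence[int],
    covariates: pd.DataFrame,
    max_iter: int = 50,
    grad_tol: float = 1e-8,
) -> CoxFit:
    """Cox proportional-hazards fit (Breslow ties, Newton-Raphson).

    Raises on zero-variance covariates; monotone likelihood (complete
    separation) is flagged rather than silently returned.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    x = covariates.to_numpy(float)
    if e.sum() < 1:
        raise ValueError("need at least one event")
    sd = x.std(axis=0)
    dead = [c for c, s in zip(covariates.columns, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance covariate(s): {dead}")
    center = x.mean(axis=0)
    xc = x - center  # centering stabilizes exp() without changing beta
    beta = np.zeros(x.shape[1])
    ll, grad, hess = _cox_quantities(beta, xc, t, e)
    converged, n_iter = False, 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        new_beta = beta - step
        new_ll, new_grad, new_hess = _cox_quantities(new_beta, xc, t, e)
        halvings = 0
        while new_ll < ll and halvings < 20:  # step-halving safeguard
            step /= 2
            new_beta = beta - step
            new_ll, new_grad, new_hess = _cox_quantities(new_beta, xc, t, e)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.linalg.norm(grad) < grad_tol:
            converged = True
            break
    separation = bool(np.abs(beta).max() > 20)
    if separation:
        warnings.warn("possible monotone likelihood (complete separation) in Cox fit", stacklevel=2)
    cov = np.linalg.pinv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    cols = covariates.columns
    return CoxFit(
        coef=pd.Series(beta, index=cols),
        se=pd.Series(se, index=cols),
        p_values=pd.Series(p, index=cols),
        log_likelihood=float(ll),
        converged=converged,
        n_iter=n_iter,
        separation_flag=separation,
    )


def hotspot_cohort_filter(clinical: pd.DataFrame) -> pd.Index:
    """Samples retained for hotspot-group survival comparisons.

    Drops pre/minimally invasive cases (AAH/AIS/MIA) and relapse-free
    pathological stage I patients who received no adjuvant therapy; every
    other sample is kept.
    """
    needed = ["stage", "relapse", "adjuvant"]
    missing = [c for c in needed if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    stage = clinical["stage"].astype(str).str.upper()
    relapse = clinical["relapse"].astype(int)
    adjuvant = clinical["adjuvant"].astype(int)
    drop = stage.isin(PREINVASIVE_STAGES) | (stage.isin(STAGE_I) & (relapse == 0) & (adjuvant == 0))
    return clinical.index[~drop]


def median_split(values: pd.Series, labels: tuple[str, str] = ("high", "low")) -> pd.Series:
    """Split samples at the median: strictly above -> 'high', ties at the
    median go to 'low'.  Degenerate (constant) vectors raise."""
    if values.nunique() < 2:
        raise ValueError("cannot median-split a constant vector")
    med = values.median()
    out = pd.Series(np.where(values > med, labels[0], labels[1]), index=values.index, name="split")
    if out.nunique() < 2:
        raise ValueError("median split produced a single group")
    return out


@dataclass
class GroupComparison:
    endpoint: str
    curves: dict[str, KmCurve] = field(default_factory=dict)
    logrank_statistic: float = np.nan
    logrank_df: int = 0
    logrank_p: float = np.nan
    cox: CoxFit | None = None
    reference_group: str | None = None


def compare_groups(
    clinical: pd.DataFrame,
    groups: pd.Series | Mapping[str, str],
    endpoints: Sequence[str] = ("os", "rfs"),
    reference: str | None = None,
) -> dict[str, GroupComparison]:
    """Per-endpoint KM curves, log-rank test and Cox hazard ratios by group.

    ``clinical`` must carry '<endpoint>_time' / '<endpoint>_event' columns;
    ``groups`` labels every analyzed sample.  Cox uses dummy covariates
    against the reference group (first label in sorted order by default), so
    coefficients are log hazard ratios vs that reference.
    """
    g = pd.Series(groups)
    g = g.reindex(clinical.index).dropna()
    labels = sorted(g.unique())
    if len(labels) < 2:
        raise ValueError("grouping must define >= 2 groups")
    ref = reference if reference is not None else labels[0]
    if ref not in labels:
        raise ValueError(f"reference group {ref!r} not present")
    out: dict[str, GroupComparison] = {}
    for ep in endpoints:
        tcol, ecol = f"{ep}_time", f"{ep}_event"
        if tcol not in clinical.columns or ecol not in clinical.columns:
            raise ValueError(f"clinical table missing {tcol}/{ecol}")
        sub = clinical.loc[g.index]
        t = sub[tcol].to_numpy(float)
        e = sub[ecol].to_numpy(int)
        comp = GroupComparison(endpoint=ep)
        for lab in labels:
            mask = (g == lab).to_numpy()
            comp.curves[lab] = km_estimate(t[mask], e[mask])
        comp.logrank_statistic, comp.logrank_df, comp.logrank_p = logrank_test(t, e, g)
        dummies = pd.get_dummies(g, dtype=float).drop(columns=[ref])
        comp.cox = cox_fit(t, e, dummies)
        comp.reference_group = ref
        out[ep] = comp
    return out
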