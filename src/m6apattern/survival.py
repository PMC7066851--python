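"""Survival machinery: Kaplan-Meier, log-rank, Cox PH, gene screening, and
maximally selected rank-statistic cutpoints.

The Cox model maximizes the Breslow partial likelihood by Newton-Raphson
with step-halving.  The cutpoint search standardizes the two-group log-rank
statistic at every admissible split of a continuous score and picks the
maximizer; no p-value is attached to the maximal statistic because the
selection process inflates its null distribution far beyond the nominal
chi-square (downstream Kaplan-Meier contrasts on the chosen groups are
descriptive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate: a right-continuous step function."""

    times: np.ndarray        # distinct event times, ascending
    at_risk: np.ndarray      # n_i just before each event time
    events: np.ndarray       # d_i at each event time
    survival: np.ndarray     # S(t_i)
    var_greenwood: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times <= 0).any():
        raise ValueError("survival times must be > 0")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return times, events.astype(int)


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance."""
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="mergesort")
    t_sorted, e_sorted = times[order], events[order]
    event_times = np.unique(t_sorted[e_sorted == 1])
    n = times.size
    at_risk = np.empty(event_times.size)
    d = np.empty(event_times.size)
    for i, t in enumerate(event_times):
        at_risk[i] = np.sum(t_sorted >= t)
        d[i] = np.sum((t_sorted == t) & (e_sorted == 1))
    surv = np.cumprod(1.0 - d / at_risk)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.nan)
    var = surv**2 * np.cumsum(gw_terms)
    return KMCurve(
        times=event_times, at_risk=at_risk, events=d, survival=surv, var_greenwood=var
    )


def survival_at(curve: KMCurve, t: float) -> float:
    return curve.survival_at(t)


# --------------------------------------------------------------------------
# Log-rank test
# --------------------------------------------------------------------------

@dataclass
class LogrankResult:
    groups: list
    observed: np.ndarray
    expected: np.ndarray
    o_minus_e: np.ndarray
    variance: np.ndarray   # (k-1) x (k-1) covariance of the first k-1 groups
    chisq: float
    df: int
    p: float


def logrank_test(times, events, groups) -> LogrankResult:
    """k-group log-rank test from hypergeometric expectations per event time."""
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    for lv in levels:
        if not np.any(groups == lv):
            raise ValueError(f"group {lv!r} is empty")
    k = len(levels)
    G = np.column_stack([(groups == lv).astype(float) for lv in levels])

    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k - 1, k - 1))
    for t in event_times:
        at_risk = times >= t
        n_t = at_risk.sum()
        d_t = np.sum((times == t) & (events == 1))
        n_g = G[at_risk].sum(axis=0)
        d_g = G[(times == t) & (events == 1)].sum(axis=0)
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            scale = d_t * (n_t - d_t) / (n_t - 1)
            v = scale * (np.diag(frac) - np.outer(frac, frac))
            V += v[: k - 1, : k - 1]
    diff = (O - E)[: k - 1]
    try:
        chisq = float(diff @ np.linalg.solve(V, diff))
    except np.linalg.LinAlgError:
        chisq = float(diff @ np.linalg.pinv(V) @ diff)
    chisq = max(chisq, 0.0)
    p = float(stats.chi2.sf(chisq, k - 1))
    return LogrankResult(
        groups=levels,
        observed=O,
        expected=E,
        o_minus_e=O - E,
        variance=V,
        chisq=chisq,
        df=k - 1,
        p=p,
    )


# --------------------------------------------------------------------------
# Cox proportional hazards (Breslow partial likelihood)
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    n_iter: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "z": self.z,
                "p": self.p,
            },
            index=self.names,
        )


def _breslow_loglik(beta, t_desc, e_desc, X_desc, risk_end, ev_groups):
    """Log partial likelihood, score and information at ``beta``.

    Input is sorted by descending time so cumulative sums over positions
    0..risk_end give risk-set aggregates; ties share a risk set (Breslow).
    """
    eta = X_desc @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    cw = np.cumsum(w)
    cwx = np.cumsum(w[:, None] * X_desc, axis=0)
    p_dim = X_desc.shape[1]
    cwxx = np.cumsum(
        w[:, None, None] * (X_desc[:, :, None] * X_desc[:, None, :]), axis=0
    )
    ll = 0.0
    score = np.zeros(p_dim)
    info = np.zeros((p_dim, p_dim))
    for re_idx, d_j, x_sum, eta_sum in ev_groups:
        s0 = cw[re_idx]
        s1 = cwx[re_idx]
        s2 = cwxx[re_idx]
        ll += eta_sum - d_j * np.log(s0)
        xbar = s1 / s0
        score += x_sum - d_j * xbar
        info += d_j * (s2 / s0 - np.outer(xbar, xbar))
    return ll, score, info


def _prepare_cox(times, events, X):
    order = np.argsort(-times, kind="mergesort")
    t_desc, e_desc, X_desc = times[order], events[order], X[order]
    ev_groups = []
    for t in np.unique(t_desc[e_desc == 1]):
        mask = (t_desc == t) & (e_desc == 1)
        risk_end = np.searchsorted(-t_desc, -t, side="right") - 1
        ev_groups.append((risk_end, float(mask.sum()), X_desc[mask].sum(axis=0), None))
    return t_desc, e_desc, X_desc, ev_groups


def cox_fit(
    times,
    events,
    covariates,
    names: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Cox PH fit by Newton-Raphson on the Breslow partial likelihood.

    Step-halving guards against likelihood decreases; convergence is
    declared when the max absolute score component drops below ``tol``.
    A monotone (separated) likelihood is flagged as non-converged with the
    coefficient capped at |beta| = 20.
    """
    times, events = _check_surv(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    sds = X.std(axis=0)
    if (sds == 0).any():
        j = int(np.argwhere(sds == 0)[0, 0])
        label = names[j] if names else f"column {j}"
        raise ValueError(f"zero-variance covariate: {label}")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]

    # center for numerical stability; partial likelihood is shift-invariant
    X_c = X - X.mean(axis=0)
    t_desc, e_desc, X_desc, ev_raw = _prepare_cox(times, events, X_c)
    # precompute per-event-time linear sums of covariates over events
    ev_groups = []
    for re_idx, d_j, x_sum, _ in ev_raw:
        ev_groups.append((re_idx, d_j, x_sum, x_sum))  # eta_sum set per-beta below

    def evaluate(beta):
        # recompute eta_sum = sum over events of x'beta at this beta
        groups = [
            (re_idx, d_j, x_sum, float(x_sum @ beta))
            for re_idx, d_j, x_sum, _ in ev_groups
        ]
        return _breslow_loglik(beta, t_desc, e_desc, X_desc, None, groups)

    beta = np.zeros(X.shape[1])
    ll, score, info = evaluate(beta)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving on likelihood decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, score_new, info_new = evaluate(cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if np.max(np.abs(beta)) > 20.0:
            logger.warning(
                "Cox fit diverging (|beta| > 20): likely monotone likelihood"
            )
            beta = np.clip(beta, -20.0, 20.0)
            ll, score, info = evaluate(beta)
            converged = False
            break
    else:
        it = max_iter
    if np.max(np.abs(score)) < tol:
        converged = True

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(beta.size, np.nan)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = beta / se
        ci_lower = np.exp(beta - 1.96 * se)
        ci_upper = np.exp(beta + 1.96 * se)  # inf when separated
    p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(
        names=list(names),
        beta=beta,
        se=se,
        hr=np.exp(beta),
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        z=z,
        p=p,
        loglik=float(ll),
        loglik_null=float(ll_null),
        converged=converged,
        n_iter=it,
    )


def encode_covariates(clinical: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Design matrix for a multivariable Cox model.

    Numeric columns pass through; categorical columns are one-hot encoded
    with the lexicographically first level as the reference.
    """
    parts = []
    for col in columns:
        s = clinical[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).rename(col))
        else:
            levels = sorted(s.astype(str).unique())
            for lv in levels[1:]:
                parts.append((s.astype(str) == lv).astype(float).rename(f"{col}[{lv}]"))
    return pd.concat(parts, axis=1)


def cox_screen(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    gene_ids,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate Cox screen of genes on their z-scored expression.

    A gene is kept when its Wald p is below ``alpha`` and the fit
    converged; non-converged fits are flagged and never kept.
    """
    gene_ids = list(gene_ids)
    missing = [g for g in gene_ids if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    samples = list(expr.columns)
    if list(clinical.index) != samples:
        clinical = clinical.loc[samples]
    times = clinical["os_time"].to_numpy(dtype=float)
    events = clinical["os_event"].to_numpy(dtype=int)
    rows = []
    for g in gene_ids:
        x = expr.loc[g].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            rows.append((g, np.nan, np.nan, np.nan, np.nan, np.nan, False, False))
            logger.warning("gene %r has zero variance; flagged, not kept", g)
            continue
        z = (x - x.mean()) / sd
        fit = cox_fit(times, events, z, names=[g])
        keep = bool(fit.converged and fit.p[0] < alpha)
        rows.append(
            (
                g,
                float(fit.beta[0]),
                float(fit.hr[0]),
                float(fit.ci_lower[0]),
                float(fit.ci_upper[0]),
                float(fit.p[0]),
                bool(fit.converged),
                keep,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "beta", "hr", "ci_lower", "ci_upper", "p", "converged", "keep"],
    ).set_index("gene")


# --------------------------------------------------------------------------
# Maximally selected rank statistics
# --------------------------------------------------------------------------

@dataclass
class CutpointResult:
    candidates: np.ndarray     # admissible cutpoint values, ascending
    statistics: np.ndarray     # standardized log-rank z per candidate
    cutpoint: float            # c* maximizing |z| (tie: smaller c)
    max_stat: float            # |z(c*)|
    minprop: float
    n_low: int
    n_high: int


def max_stat_cutpoint(score, times, events, minprop: float = 0.1) -> CutpointResult:
    """Maximally selected two-group log-rank statistic over score cutpoints.

    Candidates are distinct observed score values whose low group
    {score <= c} and high group {score > c} both contain at least
    ceil(minprop * n) samples.  The returned groups are rank-based, so the
    result is invariant under strictly monotone transforms of the score.
    """
    score = np.asarray(score, dtype=float)
    times, events = _check_surv(times, events)
    n = score.size
    gmin = int(np.ceil(minprop * n))
    order = np.argsort(score, kind="mergesort")
    s_sorted = score[order]

    event_times = np.unique(times[events == 1])
    J = event_times.size
    if J == 0:
        raise ValueError("no events; log-rank undefined")
    # J x n indicators in score-sorted sample order
    at_risk = times[order][None, :] >= event_times[:, None]
    death = (times[order][None, :] == event_times[:, None]) & (
        events[order][None, :] == 1
    )
    cum_risk = np.cumsum(at_risk, axis=1)       # n1_j(k): low group size k
    cum_death = np.cumsum(death, axis=1)
    n_j = cum_risk[:, -1].astype(float)
    d_j = cum_death[:, -1].astype(float)

    # split after position k (low group = first k sorted samples)
    ks = np.arange(gmin, n - gmin + 1)
    ks = ks[ks < n]
    # candidate is valid only at a distinct-value boundary
    distinct = s_sorted[ks - 1] < s_sorted[np.minimum(ks, n - 1)]
    ks = ks[distinct]
    if ks.size < 1:
        raise ValueError("no admissible cutpoint under the minprop constraint")

    n1 = cum_risk[:, ks - 1].astype(float)      # J x len(ks)
    d1 = cum_death[:, ks - 1].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = d_j[:, None] * n1 / n_j[:, None]
        frac = n1 / n_j[:, None]
        vterm = (
            d_j[:, None]
            * frac
            * (1.0 - frac)
            * (n_j[:, None] - d_j[:, None])
            / np.maximum(n_j[:, None] - 1.0, 1.0)
        )
    o_minus_e = np.nansum(d1 - e1, axis=0)
    var = np.nansum(vterm, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, o_minus_e / np.sqrt(var), 0.0)

    candidates = s_sorted[ks - 1]
    best = int(np.argmax(np.abs(z)))  # first max -> smaller candidate
    cstar = float(candidates[best])
    n_low = int(np.sum(score <= cstar))
    return CutpointResult(
        candidates=candidates,
        statistics=z,
        cutpoint=cstar,
        max_stat=float(np.abs(z[best])),
        minprop=minprop,
        n_low=n_low,
        n_high=n - n_low,
    )
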