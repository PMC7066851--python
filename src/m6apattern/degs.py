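"""Phenotype-related gene discovery.

Moderated two-sample t-tests with empirical-Bayes variance shrinkage
(the limma-style estimator), Benjamini-Hochberg control, intersection of
pairwise DEG sets across modification patterns, and hypergeometric
over-representation analysis on user-supplied gene sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

_DF_INF = 1e7  # working stand-in for an infinite prior df


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_prior(s2: np.ndarray, d_g: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on the log sample variances.

    Moments of log s^2 under the scaled chi-square model: the excess
    variance of e = log s^2 - digamma(d_g/2) + log(d_g/2) over
    trigamma(d_g/2) estimates trigamma(d0/2).  A non-positive excess means
    the variances are already homogeneous; the prior df is then infinite
    (full shrinkage) and the prior variance is the plain mean of the sample
    variances, matching the standard moderated-t estimator.
    """
    e = np.log(s2) - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_mean = float(np.mean(e))
    if e.size < 2:
        return np.inf, float(np.mean(s2))
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, d_g / 2.0))
    if excess <= 0:
        logger.info("no excess variance in log s^2; prior df set to infinity")
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(
        np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, s0_2


def shrink_variance(s2, d_g: float, d0: float, s0_2: float):
    """Posterior (shrunk) variance (d0*s0^2 + d_g*s2) / (d0 + d_g).

    d0 = 0 recovers the sample variance; d0 = inf collapses to the prior.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_2)
    return (d0 * s0_2 + d_g * s2) / (d0 + d_g)


def moderated_ttest(
    expr: pd.DataFrame, samples_a, samples_b
) -> pd.DataFrame:
    """Per-gene moderated t-test between two sample groups.

    Pooled-variance two-sample design; gene variances are shrunk toward a
    common prior, s2_post = (d0*s0^2 + d_g*s2_g) / (d0 + d_g), with the
    prior (d0, s0^2) fit by method of moments on the log sample variances.
    The moderated t has d0 + d_g degrees of freedom.  BH-adjusted p-values
    are appended over all genes.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 samples per group")
    A = expr.loc[:, samples_a].to_numpy(dtype=float)
    B = expr.loc[:, samples_b].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    d_g = na + nb - 2
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + (
        (B - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / d_g
    c = np.sqrt(1.0 / na + 1.0 / nb)
    diff = mean_a - mean_b

    positive = s2 > 0
    if positive.any():
        d0, s0_2 = _fit_prior(s2[positive], d_g)
    else:
        d0, s0_2 = np.inf, 0.0
    d0_eff = min(d0, _DF_INF)
    s2_post = (d0_eff * s0_2 + d_g * s2) / (d0_eff + d_g)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = np.where(s2 > 0, diff / (np.sqrt(s2) * c), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
        t_mod = np.where(s2_post > 0, diff / (np.sqrt(s2_post) * c), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    df_total = min(d0 + d_g, _DF_INF)
    p = np.where(
        np.isfinite(t_mod), 2.0 * stats.t.sf(np.abs(t_mod), df_total), 0.0
    )
    p = np.where((diff == 0) & (s2_post == 0), 1.0, p)

    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log_fc": diff,
            "t": t_ord,
            "t_mod": t_mod,
            "df_resid": float(d_g),
            "df_prior": d0,
            "s2": s2,
            "s2_prior": s0_2,
            "s2_post": s2_post,
            "p": p,
        },
        index=expr.index.copy(),
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def deg_overlap(
    tables: dict[str, pd.DataFrame] | list[pd.DataFrame],
    alpha: float = 0.001,
    mode: str = "intersection",
) -> list[str]:
    """Genes differentially expressed in every pairwise comparison.

    Each table's DEG set is {gene : adjusted p < alpha}; by default the
    sets are intersected across all comparisons (``mode="union"`` unions
    them instead).  The result is sorted lexicographically.
    """
    if isinstance(tables, dict):
        tables = list(tables.values())
    if len(tables) < 2:
        raise ValueError("need >= 2 DEG tables")
    universe = set(tables[0].index)
    for t in tables[1:]:
        if set(t.index) != universe:
            raise ValueError("DEG tables cover different gene universes")
    sets = [set(t.index[t["p_adj"] < alpha]) for t in tables]
    if mode == "intersection":
        result = set.intersection(*sets)
    elif mode == "union":
        result = set.union(*sets)
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    return sorted(result)


def ora_hypergeometric(
    hits, universe, sets: GeneSetCollection | dict
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each gene set.

    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|set & universe|,
    n=|hits|); BH adjustment across sets.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    if isinstance(sets, GeneSetCollection):
        items = sets.items()
    else:
        items = sets.items()
    rows = []
    N, n = len(universe), len(hits)
    for name, members in items:
        K = len(set(members) & universe)
        k = len(set(members) & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append((name, K, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out.set_index("set")
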