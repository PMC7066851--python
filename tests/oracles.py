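"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: full running-sum vectors, exhaustive
enumeration, grid search.  None of it shares code with the package.
"""

from __future__ import annotations

from math import comb

import numpy as np


def ssgsea_es_bruteforce(values, gene_ids, members, alpha=0.25):
    """Enrichment score for one sample by materializing the full running sums.

    ``values``/``gene_ids`` describe the sample; ``members`` is the gene
    set.  Ties are broken by lexicographic gene id.
    """
    order = sorted(range(len(values)), key=lambda i: (-values[i], gene_ids[i]))
    n = len(values)
    in_set = [gene_ids[i] in set(members) for i in order]
    weights = [(n - pos) ** alpha for pos in range(n)]  # z = N, N-1, ..., 1
    total_in = sum(w for w, m in zip(weights, in_set) if m)
    n_out = n - sum(in_set)
    p_in = []
    p_out = []
    run_in = 0.0
    run_out = 0
    for pos in range(n):
        if in_set[pos]:
            run_in += weights[pos]
        else:
            run_out += 1
        p_in.append(run_in / total_in)
        p_out.append(run_out / n_out)
    return sum(pi - po for pi, po in zip(p_in, p_out))


def fisher_two_sided_enum(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with the fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if 0 in (r1, r2, c1, b + d):
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    probs = [comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-12))


def bh_step_up(pvals):
    """Benjamini-Hochberg by the literal step-up formula."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return adj


def hypergeom_upper_tail(k, N, K, n):
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by direct summation."""
    denom = comb(N, n)
    return sum(
        comb(K, x) * comb(N - K, n - x) / denom
        for x in range(k, min(K, n) + 1)
    )


def cox_grid_beta(times, events, x, lo=-3.0, hi=3.0, step=1e-3):
    """Univariate Cox estimate by grid search on the Breslow partial
    log-likelihood."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)

    def ll(beta):
        total = 0.0
        for t in np.unique(times[events == 1]):
            at_risk = times >= t
            dead = (times == t) & (events == 1)
            total += beta * x[dead].sum() - dead.sum() * np.log(
                np.sum(np.exp(beta * x[at_risk]))
            )
        return total

    grid = np.arange(lo, hi + step, step)
    return grid[int(np.argmax([ll(b) for b in grid]))]


def logrank_z_two_group(times, events, in_group1):
    """Standardized two-group log-rank statistic (O1-E1)/sqrt(V), naive."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g1 = np.asarray(in_group1, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        dead = (times == t) & (events == 1)
        n_t = at_risk.sum()
        d_t = dead.sum()
        n1 = (at_risk & g1).sum()
        d1 = (dead & g1).sum()
        o_minus_e += d1 - d_t * n1 / n_t
        if n_t > 1:
            var += d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    return o_minus_e / np.sqrt(var) if var > 0 else 0.0


def km_survival_empirical(times, t):
    """Empirical survival P(T > t) for fully observed (uncensored) times."""
    times = np.asarray(times, float)
    return float(np.mean(times > t))
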