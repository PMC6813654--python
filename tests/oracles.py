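"""Independent brute-force oracles used to pin expected values.

These deliberately avoid the library code paths they check: the Cox
oracle maximises the Efron partial likelihood by dense grid search, the
concordance oracle enumerates all pairs with explicit loops, the Fisher
oracle enumerates the full hypergeometric support, and the
Kaplan-Meier / chi-square oracles apply the textbook formulas directly.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def efron_partial_loglik(betas, x, times, events):
    """Efron-tie partial log-likelihood of a single covariate, vectorized
    over a grid of coefficients."""
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    expx = np.exp(np.outer(x, betas))  # n x B
    ll = np.zeros_like(betas)
    for u in np.unique(times[events == 1]):
        dead = (times == u) & (events == 1)
        at_risk = times >= u
        d = int(dead.sum())
        ll += betas * x[dead].sum()
        risk_sum = expx[at_risk].sum(axis=0)
        dead_sum = expx[dead].sum(axis=0)
        for ell in range(d):
            ll -= np.log(risk_sum - (ell / d) * dead_sum)
    return ll


def cox_coef_grid_search(x, times, events, lo=-5.0, hi=5.0, step=1e-4):
    """Argmax of the Efron partial likelihood over a dense grid."""
    grid = np.arange(lo, hi + step / 2, step)
    ll = efron_partial_loglik(grid, x, times, events)
    return float(grid[int(np.argmax(ll))])


def concordance_brute_force(risk, times, events):
    """Harrell's C by explicit enumeration of all ordered pairs."""
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(times)
    comparable = concordant = tied = 0
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                comparable += 1
                if risk[i] > risk[j]:
                    concordant += 1
                elif risk[i] == risk[j]:
                    tied += 1
    if comparable == 0:
        raise ZeroDivisionError("no comparable pair")
    return (concordant + 0.5 * tied) / comparable


def fisher_two_sided_enumeration(table, rel_tol=1e-7):
    """Two-sided Fisher p by full enumeration of the hypergeometric
    support at fixed margins (minimum-likelihood convention)."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1.0 + rel_tol):
            total += pk
    return float(min(total, 1.0))


def km_product_limit(times, events):
    """Kaplan-Meier by the textbook product-limit formula; returns
    (event_times, survival_after_each)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out_t, out_s = [], []
    s = 1.0
    for u in sorted(set(times[events == 1])):
        at_risk = int((times >= u).sum())
        d = int(((times == u) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        out_t.append(u)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def chi_square_stat(table):
    """Pearson chi-square statistic by direct O/E summation."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


def pooled_t_stat(x, y):
    """Textbook pooled-variance two-sample t statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return float((x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny)))


def bh_step_up(pvals):
    """Benjamini-Hochberg adjusted p-values by the hand step-up rule."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj
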