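"""Slow, independent reference implementations used only to check the
package's fast paths. Deliberately written with explicit Python loops and
different library calls than the implementations they validate."""

import numpy as np
from scipy.stats import norm


def gsva_naive(x, gene_sets_idx, kcdf="gaussian", tau=1.0, mode="max_diff"):
    """Naive per-sample GSVA: loops over genes, samples and sets.

    ``x``: genes x samples; ``gene_sets_idx``: dict name -> list of row
    indices. Returns dict name -> per-sample score array.
    """
    p, n = x.shape
    z = np.empty((p, n))
    for i in range(p):
        if kcdf == "gaussian":
            sd = np.std(x[i], ddof=1)
            if sd == 0:
                z[i] = 0.5
                continue
            h = sd / 4.0
            for j in range(n):
                z[i, j] = np.mean([norm.cdf((x[i, j] - x[i, k]) / h)
                                   for k in range(n)])
        elif kcdf == "ecdf":
            for j in range(n):
                z[i, j] = np.mean([x[i, k] <= x[i, j] for k in range(n)])
        else:
            raise ValueError(kcdf)

    out = {}
    for name, idx in gene_sets_idx.items():
        in_set = np.zeros(p, dtype=bool)
        in_set[idx] = True
        k = in_set.sum()
        scores = np.empty(n)
        for j in range(n):
            order = sorted(range(p), key=lambda g: (-z[g, j], g))
            rank_of = {g: t + 1 for t, g in enumerate(order)}
            r = {g: abs(p / 2.0 - rank_of[g]) ** tau for g in range(p)}
            denom = sum(r[g] for g in range(p) if in_set[g])
            v, vmax, vmin = 0.0, 0.0, 0.0
            for g in order:
                if in_set[g]:
                    v += r[g] / denom
                else:
                    v -= 1.0 / (p - k)
                vmax = max(vmax, v)
                vmin = min(vmin, v)
            if mode == "max_diff":
                scores[j] = vmax + vmin
            else:
                scores[j] = vmax if vmax >= -vmin else vmin
        out[name] = scores
    return out


def bh_naive(p):
    """Direct definition: q_i = min over j with p_(j) >= p_(i) of
    p_(j) * m / rank(j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, i in enumerate(order):
        q[i] = min(min(p[order[j]] * m / (j + 1) for j in range(pos, m)), 1.0)
    return q


def rank_sum_exact_naive(a, b):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = len(a)
    obs = ranks[:n].sum()
    mean = n * (len(pooled) + 1) / 2.0
    dev = abs(obs - mean)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= dev - 1e-9:
            hits += 1
    return hits / total
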