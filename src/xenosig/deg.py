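"""Two-group differential expression: Wilcoxon rank-sum tests, log2 fold
changes on de-logged normalized means, Benjamini-Hochberg adjustment, and
signature calling at log2FC > 0.3 (or < -0.3) with FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata

__all__ = ["DegSignature", "rank_sum_test", "log2_fold_change", "bh_adjust",
           "call_degs", "differential_expression"]

_EXACT_MAX = 8


@dataclass
class DegSignature:
    up: list
    down: list
    table: pd.DataFrame
    lfc_threshold: float = 0.3
    alpha: float = 0.05


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation enumeration when both groups have <= 8 observations
    (correct under ties); otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    obs = ranks[:n].sum()
    mean = n * (n + m + 1) / 2.0
    if n <= _EXACT_MAX and m <= _EXACT_MAX:
        dev = abs(obs - mean)
        total = comb(n + m, n)
        hits = sum(1 for idx in combinations(range(n + m), n)
                   if abs(ranks[list(idx)].sum() - mean) >= dev - 1e-9)
        return hits / total
    # tie-corrected variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / ((n + m) * (n + m - 1.0))
    var = n * m / 12.0 * (n + m + 1.0 - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(obs - mean) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def _rank_sum_matrix(xa, xb):
    """Vectorized two-sided rank-sum p per column (normal approximation)."""
    n, m = xa.shape[0], xb.shape[0]
    pooled = np.vstack([xa, xb])
    ranks = rankdata(pooled, axis=0)
    obs = ranks[:n].sum(axis=0)
    mean = n * (n + m + 1) / 2.0
    # per-column tie correction
    srt = np.sort(pooled, axis=0)
    tie_term = np.empty(pooled.shape[1])
    nm = n + m
    for j in range(pooled.shape[1]):
        _, counts = np.unique(srt[:, j], return_counts=True)
        tie_term[j] = np.sum(counts.astype(float) ** 3 - counts) / (nm * (nm - 1.0))
    var = n * m / 12.0 * (nm + 1.0 - tie_term)
    z = np.zeros_like(obs, dtype=float)
    ok = var > 0
    z[ok] = (np.abs(obs[ok] - mean) - 0.5) / np.sqrt(var[ok])
    p = np.ones_like(z)
    p[ok] = np.minimum(1.0, 2.0 * norm.sf(np.maximum(z[ok], 0.0)))
    return p


def log2_fold_change(a, b, pseudocount=1e-9):
    """log2 ratio of de-logged group means of log-normalized expression.

    ``a``/``b`` are 1-D vectors or (cells x genes) matrices of log1p
    normalized values; returns a scalar or per-gene vector.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    ma = np.expm1(a).mean(axis=0)
    mb = np.expm1(b).mean(axis=0)
    out = np.log2((ma + pseudocount) / (mb + pseudocount))
    return float(out[0]) if out.size == 1 else out


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted q-values (monotone, in [0,1])."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_degs(table: pd.DataFrame, lfc_threshold=0.3, alpha=0.05) -> DegSignature:
    """Split a (gene, log2fc, p, q) table into up/down lists.

    Strict inequalities at both thresholds: log2fc must exceed the
    threshold (or fall below its negative) and q must be below alpha.
    """
    for col in ("log2fc", "q"):
        if col not in table.columns:
            raise ValueError(f"DEG table lacks column {col!r}")
    up_mask = (table["log2fc"] > lfc_threshold) & (table["q"] < alpha)
    down_mask = (table["log2fc"] < -lfc_threshold) & (table["q"] < alpha)
    table = table.copy()
    table["call"] = np.where(up_mask, "up", np.where(down_mask, "down", "ns"))
    return DegSignature(
        up=list(table.index[up_mask]),
        down=list(table.index[down_mask]),
        table=table,
        lfc_threshold=lfc_threshold,
        alpha=alpha,
    )


def differential_expression(lognorm, genes, mask_a, mask_b, lfc_threshold=0.3,
                            alpha=0.05, min_frac=0.10,
                            pseudocount=1e-9) -> DegSignature:
    """Full two-group DEG run over a log-normalized matrix.

    Genes detected in fewer than ``min_frac`` of cells in *both* groups are
    skipped before testing (set ``min_frac=0`` to disable); B-H adjustment
    runs across the tested genes.
    """
    x = sp.csr_matrix(lognorm)
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must be nonempty")
    xa = np.asarray(x[mask_a].todense())
    xb = np.asarray(x[mask_b].todense())
    genes = np.asarray(genes, dtype=object)
    frac_a = (xa > 0).mean(axis=0)
    frac_b = (xb > 0).mean(axis=0)
    tested = (frac_a >= min_frac) | (frac_b >= min_frac)
    xa_t, xb_t = xa[:, tested], xb[:, tested]
    p = _rank_sum_matrix(xa_t, xb_t)
    lfc = log2_fold_change(xa_t, xb_t, pseudocount)
    q = bh_adjust(p)
    table = pd.DataFrame({
        "log2fc": np.atleast_1d(lfc),
        "p": p,
        "q": q,
        "pct_a": frac_a[tested],
        "pct_b": frac_b[tested],
    }, index=pd.Index(genes[tested], name="gene"))
    return call_degs(table, lfc_threshold, alpha)
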