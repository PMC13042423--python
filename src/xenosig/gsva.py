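"""Gene Set Variation Analysis (GSVA), implemented from scratch.

Given an expression matrix (genes x samples), GSVA produces one enrichment
score per gene set per sample in three steps:

1. *kernel CDF transform* — each gene's value in each sample is replaced by
   a smoothed estimate of its cumulative density against that gene's
   cross-sample distribution (Gaussian kernel with bandwidth sd/4 for
   continuous log-scale input; Poisson kernel for raw counts; plain ECDF as
   a rank-invariant mode).
2. *symmetric rank statistic* — per sample, genes are ranked by the
   transformed value (descending); the statistic ``r = |p/2 - rank|``
   up-weights both tails of the profile.
3. *weighted Kolmogorov-Smirnov random walk* — walking down the per-sample
   gene ranking, in-set genes add ``r^tau`` (normalized) and out-of-set
   genes subtract ``1/(p - |set|)``; the score is the maximum positive
   deviation plus the maximum negative deviation ("max_diff" mode, the
   reference default) or the single largest-magnitude deviation
   ("two_sided_max"). Scores always lie in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import poisson

from .deg import bh_adjust

__all__ = ["GsvaParams", "GsvaResult", "kcdf_transform", "gsva_scores",
           "compare_scores"]


@dataclass
class GsvaParams:
    kcdf: str = "gaussian"
    tau: float = 1.0
    score_mode: str = "max_diff"
    min_set_size: int = 5
    max_set_size: int = 500

    def validate(self):
        if self.kcdf not in ("gaussian", "poisson", "ecdf"):
            raise ValueError(f"unknown kcdf {self.kcdf!r}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.score_mode not in ("max_diff", "two_sided_max"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        if self.min_set_size > self.max_set_size:
            raise ValueError("min_set_size must not exceed max_set_size")
        return self


@dataclass
class GsvaResult:
    scores: pd.DataFrame          # sets x samples
    params: GsvaParams
    set_sizes: dict               # genes per set after panel intersection
    errors: dict = field(default_factory=dict)
    dropped_genes: dict = field(default_factory=dict)


def kcdf_transform(expr, kcdf="gaussian") -> np.ndarray:
    """Relative-expression statistic per gene per sample, in (0, 1).

    ``expr`` is genes x samples with at least 2 samples. Constant genes map
    to 0.5 everywhere.
    """
    x = np.asarray(expr, dtype=float)
    if x.ndim != 2:
        raise ValueError("expression must be a 2-D genes x samples matrix")
    n_genes, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("kernel CDF needs at least 2 samples per gene")
    out = np.empty_like(x)
    if kcdf == "ecdf":
        for i in range(n_genes):
            out[i] = (x[i][None, :] <= x[i][:, None]).mean(axis=1)
        return out
    if kcdf == "gaussian":
        sd = x.std(axis=1, ddof=1)
        h = sd / 4.0
        const = h == 0
        # chunk genes so the (chunk, n, n) broadcast stays small
        chunk = max(1, int(4e6) // max(n_samples * n_samples, 1))
        for s in range(0, n_genes, chunk):
            e = min(s + chunk, n_genes)
            hs = np.where(const[s:e], 1.0, h[s:e])[:, None, None]
            diff = (x[s:e, :, None] - x[s:e, None, :]) / hs
            out[s:e] = ndtr(diff).mean(axis=2)
        out[const] = 0.5
        return out
    if kcdf == "poisson":
        for i in range(n_genes):
            out[i] = poisson.cdf(x[i][:, None], x[i][None, :] + 0.5).mean(axis=1)
        return out
    raise ValueError(f"unknown kcdf {kcdf!r}")


def _walk_scores(z, in_set, tau, mode):
    """Enrichment score per sample for one gene set.

    ``z``: (genes x samples) kcdf statistic; ``in_set``: boolean per gene.
    """
    p, n_samples = z.shape
    k = int(in_set.sum())
    order = np.argsort(-z, axis=0, kind="stable")       # per sample
    ranks = np.empty_like(order)
    cols = np.arange(n_samples)[None, :]
    ranks[order, cols] = np.arange(1, p + 1)[:, None]
    r = np.abs(p / 2.0 - ranks) ** tau                  # symmetric statistic
    in_sorted = in_set[order]                            # (p, samples)
    r_sorted = np.take_along_axis(r, order, axis=0)
    inc = np.where(in_sorted, r_sorted, 0.0)
    denom = inc.sum(axis=0)
    denom[denom == 0] = 1.0
    dec = np.where(in_sorted, 0.0, 1.0 / (p - k))
    walk = np.cumsum(inc / denom - dec, axis=0)
    vmax = np.maximum(walk.max(axis=0), 0.0)
    vmin = np.minimum(walk.min(axis=0), 0.0)
    if mode == "max_diff":
        return vmax + vmin
    # two_sided_max: deviation of largest magnitude
    return np.where(vmax >= -vmin, vmax, vmin)


def gsva_scores(expr, gene_names, sets, params: GsvaParams | None = None,
                sample_names=None, warn=None) -> GsvaResult:
    """Score each gene set in ``sets`` (name -> gene list) per sample.

    Sets falling outside [min_set_size, max_set_size] after intersection
    with the panel, or covering the whole panel, are recorded under
    ``result.errors`` while the remaining sets are scored.
    """
    params = (params or GsvaParams()).validate()
    x = np.asarray(expr, dtype=float)
    gene_names = list(gene_names)
    if x.shape[0] != len(gene_names):
        raise ValueError("gene_names length must match expression rows")
    z = kcdf_transform(x, params.kcdf)
    index = {g: i for i, g in enumerate(gene_names)}
    p = len(gene_names)
    rows, kept, sizes, errors, dropped = [], [], {}, {}, {}
    for name, genes in sets.items():
        uniq = list(dict.fromkeys(genes))
        idx = [index[g] for g in uniq if g in index]
        n_dropped = len(uniq) - len(idx)
        if n_dropped:
            dropped[name] = n_dropped
            if warn is not None:
                warn(f"set {name!r}: {n_dropped} genes absent from panel")
        if len(idx) == 0:
            errors[name] = "empty after intersection with panel"
            continue
        if len(idx) == p:
            errors[name] = "covers the entire gene panel"
            continue
        if not params.min_set_size <= len(idx) <= params.max_set_size:
            errors[name] = (f"size {len(idx)} outside "
                            f"[{params.min_set_size}, {params.max_set_size}]")
            continue
        in_set = np.zeros(p, dtype=bool)
        in_set[idx] = True
        rows.append(_walk_scores(z, in_set, params.tau, params.score_mode))
        kept.append(name)
        sizes[name] = len(idx)
    if sample_names is None:
        sample_names = [f"s{i}" for i in range(x.shape[1])]
    scores = pd.DataFrame(np.vstack(rows) if rows else
                          np.empty((0, x.shape[1])),
                          index=kept, columns=list(sample_names))
    return GsvaResult(scores, params, sizes, errors, dropped)


def compare_scores(scores: pd.DataFrame, labels) -> pd.DataFrame:
    """Welch t-test (two-sided) per gene set between two label groups, with
    B-H adjustment across sets."""
    from scipy.stats import ttest_ind

    labels = np.asarray(labels)
    if len(labels) != scores.shape[1]:
        raise ValueError("labels must match score columns")
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(uniq)}")
    a = scores.loc[:, labels == uniq[0]].to_numpy()
    b = scores.loc[:, labels == uniq[1]].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    t, pvals = ttest_ind(a, b, axis=1, equal_var=False)
    # identical groups yield 0/0; define t=0, p=1
    t = np.where(np.isnan(t), 0.0, t)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    return pd.DataFrame({
        "t": t, "p": pvals, "q": bh_adjust(pvals),
    }, index=scores.index)
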