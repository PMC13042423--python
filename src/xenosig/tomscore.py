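"""Tom score: per-cell similarity of human hepatocytes to mouse p16-high
(tdTomato-labeled) hepatocytes.

The mouse up/down DEG signature is converted to human symbols (homology
table or macrogene pairing), both converted lists are scored per cell with
GSVA, and the Tom score is the up-score minus the down-score. Cells are
grouped into high/medium/low Tom-score tertiles and summarized per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import crossmap
from .deg import DegSignature
from .gsva import GsvaParams, GsvaResult, gsva_scores

__all__ = ["TomScoreResult", "transfer_signature", "compute_tom_scores",
           "classify_groups", "summarize_by_cluster"]


@dataclass
class TomScoreResult:
    cells: pd.DataFrame           # gsva_up, gsva_down, tom, group per cell
    method: str                   # "mgi" | "saturn" | other tag
    pearson_r: float              # r between gsva_up and gsva_down
    gsva: GsvaResult | None = None


def transfer_signature(signature: DegSignature, method: str,
                       homology: pd.DataFrame | None = None,
                       pairs: pd.DataFrame | None = None):
    """Convert the mouse up/down lists to human gene lists.

    The two lists convert independently; any human gene produced by both an
    up and a down mouse gene is removed from both lists and reported under
    ``report["collisions"]``.
    """
    if method == "mgi":
        if homology is None:
            raise ValueError("mgi conversion needs a homology table")
        up, rep_up = crossmap.convert_symbols_mgi(signature.up, homology)
        down, rep_down = crossmap.convert_symbols_mgi(signature.down, homology)
    elif method == "saturn":
        if pairs is None:
            raise ValueError("saturn conversion needs a gene-pair table")
        up, rep_up = crossmap.convert_symbols_saturn(signature.up, pairs)
        down, rep_down = crossmap.convert_symbols_saturn(signature.down, pairs)
    else:
        raise ValueError(f"unknown conversion method {method!r}")
    collisions = sorted(set(up) & set(down))
    up = [g for g in up if g not in collisions]
    down = [g for g in down if g not in collisions]
    if not up or not down:
        raise ValueError("a converted signature list is empty")
    report = {"up": rep_up, "down": rep_down, "collisions": collisions}
    return up, down, report


def compute_tom_scores(expr, gene_names, up, down,
                       params: GsvaParams | None = None, cell_names=None,
                       method="mgi") -> TomScoreResult:
    """GSVA-score the up and down lists and take their difference.

    ``expr`` is genes x cells. The result carries the per-cell table
    (gsva_up, gsva_down, tom, group) and the Pearson correlation between
    the two GSVA scores across cells.
    """
    res = gsva_scores(expr, gene_names, {"up": up, "down": down},
                      params=params, sample_names=cell_names)
    for name in ("up", "down"):
        if name in res.errors:
            raise ValueError(f"gene set {name!r}: {res.errors[name]}")
    gsva_up = res.scores.loc["up"].to_numpy()
    gsva_down = res.scores.loc["down"].to_numpy()
    tom = gsva_up - gsva_down
    if np.ptp(gsva_up) == 0 or np.ptp(gsva_down) == 0:
        r = np.nan
    else:
        r = float(pearsonr(gsva_up, gsva_down).statistic)
    cells = pd.DataFrame({
        "gsva_up": gsva_up,
        "gsva_down": gsva_down,
        "tom": tom,
        "group": classify_groups(tom),
    }, index=res.scores.columns)
    return TomScoreResult(cells=cells, method=method, pearson_r=r, gsva=res)


def classify_groups(tom, mode="tertile", cutoffs=None) -> np.ndarray:
    """high/medium/low labels from Tom scores.

    Default: tertile split by sorted position (stable order breaks ties),
    so groups are as equal-sized as possible and never decrease with the
    score. If every score is identical all cells are "medium". With
    ``mode="fixed"``, ``cutoffs=(lo, hi)`` gives low <= lo < medium <= hi <
    high.
    """
    tom = np.asarray(tom, dtype=float)
    n = len(tom)
    if n < 3:
        raise ValueError("need at least 3 cells to form 3 groups")
    if mode == "fixed":
        if cutoffs is None or len(cutoffs) != 2:
            raise ValueError("fixed mode needs cutoffs=(lo, hi)")
        lo, hi = cutoffs
        return np.where(tom <= lo, "low",
                        np.where(tom <= hi, "medium", "high")).astype(object)
    if mode != "tertile":
        raise ValueError(f"unknown cut mode {mode!r}")
    if np.ptp(tom) == 0:
        return np.full(n, "medium", dtype=object)
    order = np.argsort(tom, kind="stable")
    labels = np.empty(n, dtype=object)
    third = n // 3
    rem = n % 3
    sizes = [third + (1 if i < rem else 0) for i in range(3)]
    bounds = np.cumsum(sizes)
    labels[order[:bounds[0]]] = "low"
    labels[order[bounds[0]:bounds[1]]] = "medium"
    labels[order[bounds[1]:]] = "high"
    return labels


def summarize_by_cluster(result: TomScoreResult, cluster_labels) -> pd.DataFrame:
    """Per-cluster mean Tom score, group fractions and size."""
    labels = np.asarray(cluster_labels)
    if len(labels) != len(result.cells):
        raise ValueError("cluster labels do not match scored cells")
    df = result.cells.copy()
    df["cluster"] = labels
    rows = []
    for c, grp in df.groupby("cluster", sort=True):
        frac = grp["group"].value_counts(normalize=True)
        rows.append({
            "cluster": c,
            "n": len(grp),
            "mean_tom": grp["tom"].mean(),
            "high_fraction": float(frac.get("high", 0.0)),
            "medium_fraction": float(frac.get("medium", 0.0)),
            "low_fraction": float(frac.get("low", 0.0)),
        })
    out = pd.DataFrame(rows).set_index("cluster")
    return out.sort_values("mean_tom", ascending=False)
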