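"""Per-cell quality control, normalization, clustering, contaminant-cluster
exclusion, zonation assignment and generic signature scoring.

QC thresholds follow the fixed-cell hepatocyte workflow this package
mirrors: a cell is *excluded* when its mitochondrial UMI fraction exceeds
the cap, its detected-gene count falls outside the window, or its total UMI
exceeds the cap — all strict, so boundary values are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "QcPreset", "PRESETS", "compute_cell_qc", "apply_qc_filter",
    "normalize_log", "select_hvg", "cluster_cells",
    "exclude_contaminant_clusters", "signature_score", "assign_zones",
    "ZONE_MARKERS_MOUSE", "ZONE_MARKERS_HUMAN",
]

ZONE_MARKERS_MOUSE = {
    "zone1": ["Sds", "Cyp2f2"],
    "zone2": ["Hamp", "Igfbp2"],
    "zone3": ["Glul", "Cyp2e1"],
}
ZONE_MARKERS_HUMAN = {z: [g.upper() for g in gs]
                      for z, gs in ZONE_MARKERS_MOUSE.items()}

CONTAMINANT_MARKERS_MOUSE = ["Ptprc", "Dcn", "Pecam1"]
CONTAMINANT_MARKERS_HUMAN = ["PTPRC", "DCN", "PECAM1"]


@dataclass(frozen=True)
class QcPreset:
    name: str
    max_mito_fraction: float | None
    min_genes: int
    max_genes: int
    max_umi: int

    def __post_init__(self):
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be below max_genes")
        if min(self.min_genes, self.max_genes, self.max_umi) <= 0:
            raise ValueError("thresholds must be positive")


PRESETS = {
    "mouse_hepatocyte": QcPreset("mouse_hepatocyte", 0.05, 2000, 10_000, 100_000),
    "mouse_hsc": QcPreset("mouse_hsc", 0.05, 2000, 7000, 50_000),
    "human_hepatocyte": QcPreset("human_hepatocyte", 0.05, 1500, 6000, 40_000),
}


def _matrix(counts):
    if isinstance(counts, ad.AnnData):
        return counts.X
    return counts


def compute_cell_qc(counts: ad.AnnData) -> pd.DataFrame:
    """detected_genes, total_umi and mito_fraction per cell.

    ``counts.var`` must carry a boolean ``mito`` flag (QC uses the flag, not
    the symbol prefix). All-zero cells get mito_fraction 0.
    """
    if "mito" not in counts.var.columns:
        raise ValueError("gene metadata lacks a 'mito' flag column")
    x = sp.csr_matrix(counts.X)
    detected = np.asarray((x > 0).sum(axis=1)).ravel()
    total = np.asarray(x.sum(axis=1)).ravel()
    mito_mask = counts.var["mito"].to_numpy(dtype=bool)
    mito_umi = np.asarray(x[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_umi / np.maximum(total, 1), 0.0)
    return pd.DataFrame({
        "detected_genes": detected.astype(np.int64),
        "total_umi": total.astype(np.int64),
        "mito_fraction": mito_frac,
    }, index=counts.obs_names)


def apply_qc_filter(qc_table: pd.DataFrame, preset) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep-mask plus per-cell exclusion reasons.

    ``preset`` is a QcPreset or a preset name. A cell is kept iff
    mito_fraction <= cap (when a cap is set), min_genes <= detected_genes
    <= max_genes, and total_umi <= max_umi.
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown QC preset {preset!r}; known: {sorted(PRESETS)}") from None
    for col in ("detected_genes", "total_umi", "mito_fraction"):
        if col not in qc_table.columns:
            raise ValueError(f"qc table lacks column {col!r}")
    reasons = pd.DataFrame(index=qc_table.index)
    reasons["high_mito"] = (
        qc_table["mito_fraction"] > preset.max_mito_fraction
        if preset.max_mito_fraction is not None else False)
    reasons["low_genes"] = qc_table["detected_genes"] < preset.min_genes
    reasons["high_genes"] = qc_table["detected_genes"] > preset.max_genes
    reasons["high_umi"] = qc_table["total_umi"] > preset.max_umi
    keep = ~reasons.any(axis=1)
    return keep.to_numpy(), reasons


def normalize_log(counts) -> sp.csr_matrix:
    """Counts-per-10k, natural log1p. All-zero cells stay all-zero."""
    x = sp.csr_matrix(_matrix(counts), dtype=np.float64, copy=True)
    total = np.asarray(x.sum(axis=1)).ravel()
    scale = np.divide(1e4, total, out=np.zeros_like(total, dtype=float),
                      where=total > 0)
    x = sp.diags(scale) @ x
    x.data = np.log1p(x.data)
    return sp.csr_matrix(x)


def select_hvg(lognorm, n_hvg: int) -> np.ndarray:
    """Indices of the top-``n_hvg`` genes by variance-to-mean dispersion."""
    x = sp.csr_matrix(lognorm)
    n = x.shape[0]
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = (sq - mean ** 2) * n / max(n - 1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(-disp, kind="stable")
    return np.sort(order[:min(n_hvg, x.shape[1])])


def cluster_cells(lognorm, n_hvg=2000, n_pcs=20, method="kmeans",
                  n_clusters=8, seed=0) -> np.ndarray:
    """HVG selection, PCA, then k-means (default) or Leiden graph clustering."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    x = sp.csr_matrix(lognorm)
    if x.shape[0] < 2:
        raise ValueError("clustering needs at least 2 cells")
    hvg = select_hvg(x, n_hvg)
    dense = np.asarray(x[:, hvg].todense())
    if np.allclose(dense, dense[0]):
        return np.zeros(x.shape[0], dtype=int)
    if n_pcs >= min(dense.shape):
        raise ValueError("n_pcs must be below min(n_cells, n_genes_used)")
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(dense)
    if method == "kmeans":
        km = KMeans(n_clusters=min(n_clusters, x.shape[0]), n_init=10,
                    random_state=seed)
        return km.fit_predict(pcs).astype(int)
    if method == "leiden":
        return _leiden(pcs, seed)
    raise ValueError(f"unknown clustering method {method!r}")


def _leiden(pcs, seed, n_neighbors=15, resolution=1.0):
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    g = kneighbors_graph(pcs, n_neighbors=min(n_neighbors, len(pcs) - 1),
                         mode="connectivity")
    g = g.maximum(g.T).tocoo()
    graph = igraph.Graph(n=len(pcs), edges=list(zip(g.row, g.col)))
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership, dtype=int)


def signature_score(lognorm, genes, gene_list, warn=None) -> np.ndarray:
    """Mean normalized expression over the listed genes present in the panel.

    Duplicates in the list are collapsed; missing genes are skipped (and
    reported through ``warn`` when given). Raises if no listed gene is
    present.
    """
    genes = pd.Index(genes)
    wanted = list(dict.fromkeys(gene_list))
    idx = [genes.get_loc(g) for g in wanted if g in genes]
    missing = [g for g in wanted if g not in genes]
    if missing and warn is not None:
        warn(f"{len(missing)} listed genes absent from panel: {missing[:5]}")
    if not idx:
        raise ValueError("none of the listed genes is present in the panel")
    x = sp.csr_matrix(lognorm)
    return np.asarray(x[:, idx].mean(axis=1)).ravel()


def exclude_contaminant_clusters(lognorm, genes, labels, markers,
                                 detected_genes=None, marker_fold=3.0,
                                 low_gene_quantile=0.10, warn=None) -> np.ndarray:
    """Boolean mask of cells in clusters judged to be hepatocytes.

    A cluster is dropped when its mean marker score exceeds ``marker_fold``
    times the across-cluster median score, or (when ``detected_genes`` is
    given) its median detected-gene count lies below the
    ``low_gene_quantile`` quantile of all cells.
    """
    labels = np.asarray(labels)
    x = sp.csr_matrix(lognorm)
    if len(labels) != x.shape[0]:
        raise ValueError("label vector does not match cell count")
    present = [g for g in markers if g in set(genes)]
    if not present:
        if warn is not None:
            warn("no contaminant marker present in panel; keeping all clusters")
        return np.ones(x.shape[0], dtype=bool)
    score = signature_score(x, genes, present, warn=warn)
    uniq = np.unique(labels)
    cluster_mean = np.array([score[labels == c].mean() for c in uniq])
    med = np.median(cluster_mean)
    drop = cluster_mean > marker_fold * max(med, 1e-12) if np.isfinite(marker_fold) \
        else np.zeros(len(uniq), dtype=bool)
    if detected_genes is not None:
        detected_genes = np.asarray(detected_genes)
        cutoff = np.quantile(detected_genes, low_gene_quantile)
        med_genes = np.array([np.median(detected_genes[labels == c]) for c in uniq])
        drop |= med_genes < cutoff
    if drop.all():
        raise ValueError("all clusters flagged as contaminants; nothing left")
    dropped = set(uniq[drop])
    return np.asarray([lab not in dropped for lab in labels], dtype=bool)


def assign_zones(lognorm, genes, marker_sets=None) -> pd.DataFrame:
    """Per-cell zonation labels from marker-set scores (argmax; ties ->
    'unassigned'). ``marker_sets`` defaults to the mouse zone markers."""
    if marker_sets is None:
        marker_sets = ZONE_MARKERS_MOUSE
    gene_set = set(genes)
    scores = {}
    for zone, markers in marker_sets.items():
        present = [g for g in markers if g in gene_set]
        if not present:
            raise ValueError(f"no marker of {zone!r} present in the panel")
        scores[zone] = signature_score(lognorm, genes, present)
    table = pd.DataFrame(scores)
    arr = table.to_numpy()
    best = arr.argmax(axis=1)
    top = arr.max(axis=1)
    n_at_top = (arr == top[:, None]).sum(axis=1)
    labels = np.asarray(list(table.columns))[best].astype(object)
    labels[n_at_top > 1] = "unassigned"
    table.insert(0, "zone", labels)
    return table
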