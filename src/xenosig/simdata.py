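"""Paired two-species synthetic hepatocyte scRNA-seq generator.

Emulates the structure the cross-species pipeline consumes: a mouse and a
human cell x gene unique-molecule count matrix with

* three liver zones expressed through canonical marker genes
  (zone 1: Sds/Cyp2f2, zone 2: Hamp/Igfbp2, zone 3: Glul/Cyp2e1, and their
  upper-case human counterparts),
* a planted p16-high-like subpopulation carrying correlated up/down gene
  programs in both species (the mouse copy is observable as a tdTomato-like
  reporter label, the human copy only through the truth table),
* mitochondrial genes (prefixed mt-/MT- and flagged in gene metadata),
* planted 1:1 orthology (plus optional many-to-many groups) with a shared
  homology class key, protein-embedding vectors that agree between ortholog
  partners up to additive noise, and
* outlier cells that each violate exactly one threshold of the QC preset
  their species will be filtered with.

Counts are gene-wise ZINB with lognormal baseline means shared between
ortholog partners, multiplicative zone/signature effects, and a per-cell
lognormal library-size factor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as xio
from .zinb import sample_zinb

__all__ = ["SimConfig", "SyntheticBundle", "simulate_bundle",
           "make_homology_table", "write_bundle"]

MOUSE_ZONE_MARKERS = {
    "zone1": ["Sds", "Cyp2f2"],
    "zone2": ["Hamp", "Igfbp2"],
    "zone3": ["Glul", "Cyp2e1"],
}
MOUSE_CONTAMINANT_MARKERS = ["Ptprc", "Dcn", "Pecam1"]

# QC presets the outlier generator targets (mirrors qc.PRESETS; duplicated
# numbers avoided by importing lazily in _preset()).


@dataclass
class SimConfig:
    """Ground-truth generator settings.

    Defaults describe the desk-scale study conditions: ~800 cells and 3500
    genes per species (enough genes that intact cells sit well inside the
    detected-gene windows of the hepatocyte QC presets), a 10% signature
    subpopulation at log2FC 1.5, even zonation, 2% baseline mitochondrial
    content, and near-duplicate protein embeddings for ortholog partners.
    """

    seed: int = 0
    n_cells_per_species: int = 800
    n_genes_per_species: int = 3500
    n_ortholog_pairs: int = 2500
    frac_signature_cells: float = 0.10
    n_up_genes: int = 60
    n_down_genes: int = 60
    signature_log2fc: float = 1.5
    zone_fractions: tuple = (1 / 3, 1 / 3, 1 / 3)
    mito_gene_count: int = 10
    zinb_dispersion: float = 2.0
    zinb_dropout: float = 0.05
    embedding_dim: int = 32
    embedding_noise_sd: float = 0.05
    n_outlier_cells: int = 15
    # secondary knobs
    zone_marker_fold: float = 8.0
    mean_log_mu: float = 1.2
    mean_log_sd: float = 0.7
    libsize_sd: float = 0.3
    libsize_clip: tuple = (0.6, 2.2)
    target_mito_fraction: float = 0.02
    m2m_fraction: float = 0.02
    unmapped_fraction: float = 0.02
    qc_preset_mouse: str = "mouse_hepatocyte"
    qc_preset_human: str = "human_hepatocyte"

    def validate(self):
        if self.n_cells_per_species <= 0 or self.n_genes_per_species <= 0:
            raise ValueError("cell and gene counts must be positive")
        if self.n_ortholog_pairs > self.n_genes_per_species:
            raise ValueError("n_ortholog_pairs cannot exceed n_genes_per_species")
        reserved = len(MOUSE_CONTAMINANT_MARKERS) + sum(
            len(v) for v in MOUSE_ZONE_MARKERS.values())
        if self.n_ortholog_pairs < reserved + self.n_up_genes + self.n_down_genes:
            raise ValueError("too few ortholog pairs for markers plus signature genes")
        if self.mito_gene_count + self.n_ortholog_pairs > self.n_genes_per_species:
            raise ValueError("mito genes plus ortholog pairs exceed the gene panel")
        for frac in (self.frac_signature_cells, self.zinb_dropout,
                     self.m2m_fraction, self.unmapped_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        zf = np.asarray(self.zone_fractions, dtype=float)
        if zf.shape != (3,) or abs(zf.sum() - 1.0) > 1e-12 or (zf < 0).any():
            raise ValueError("zone_fractions must be a nonnegative 3-vector summing to 1")
        if self.zinb_dispersion <= 0:
            raise ValueError("zinb_dispersion must be positive")
        if self.embedding_noise_sd < 0:
            raise ValueError("embedding_noise_sd must be nonnegative")
        if min(self.n_up_genes, self.n_down_genes, self.embedding_dim) < 0:
            raise ValueError("counts must be nonnegative")
        return self


@dataclass
class SyntheticBundle:
    counts_mouse: ad.AnnData
    counts_human: ad.AnnData
    homology: pd.DataFrame
    embeddings: pd.DataFrame
    truth: dict
    config: SimConfig = field(repr=False, default=None)


def _preset(name):
    from .qc import PRESETS
    return PRESETS[name]


def _gene_panel(cfg: SimConfig, rng):
    """Build the paired gene panels and per-gene truth roles."""
    zone_markers = [(g, z) for z, gs in MOUSE_ZONE_MARKERS.items() for g in gs]
    reserved = [g for g, _ in zone_markers] + MOUSE_CONTAMINANT_MARKERS
    n_generic = cfg.n_ortholog_pairs - len(reserved)
    generic = [f"Sim{i:05d}" for i in range(n_generic)]
    mouse_orth = reserved + generic
    human_orth = [g.upper() for g in mouse_orth]

    n_orphan = cfg.n_genes_per_species - cfg.n_ortholog_pairs - cfg.mito_gene_count
    if n_orphan < 0:
        raise ValueError("gene panel too small")
    mouse_orphan = [f"Orph{i:05d}" for i in range(n_orphan)]
    human_orphan = [f"HORPH{i:05d}" for i in range(n_orphan)]
    mouse_mito = [f"mt-Sim{i:02d}" for i in range(cfg.mito_gene_count)]
    human_mito = [f"MT-SIM{i:02d}" for i in range(cfg.mito_gene_count)]

    mouse_genes = mouse_orth + mouse_orphan + mouse_mito
    human_genes = human_orth + human_orphan + human_mito

    roles = np.array(["null"] * len(mouse_genes), dtype=object)
    for g, z in zone_markers:
        roles[mouse_genes.index(g)] = f"{z}_marker"
    for g in MOUSE_CONTAMINANT_MARKERS:
        roles[mouse_genes.index(g)] = "contaminant_marker"
    # signature genes drawn from generic orthologs only
    generic_idx = np.arange(len(reserved), cfg.n_ortholog_pairs)
    chosen = rng.choice(generic_idx, size=cfg.n_up_genes + cfg.n_down_genes,
                        replace=False)
    roles[chosen[:cfg.n_up_genes]] = "up"
    roles[chosen[cfg.n_up_genes:]] = "down"
    roles[cfg.n_genes_per_species - cfg.mito_gene_count:] = "mito"

    partner = np.array([""] * len(mouse_genes), dtype=object)
    partner[:cfg.n_ortholog_pairs] = human_orth
    gene_truth = pd.DataFrame({
        "mouse_symbol": mouse_genes,
        "human_symbol_partner": partner,
        "role": roles,
    })
    return mouse_genes, human_genes, gene_truth


def _cell_truth(cfg: SimConfig, rng, species):
    n = cfg.n_cells_per_species
    zones = rng.choice(["zone1", "zone2", "zone3"], size=n,
                       p=np.asarray(cfg.zone_fractions, dtype=float))
    n_sig = int(round(cfg.frac_signature_cells * n))
    sig = np.zeros(n, dtype=bool)
    # signature cells live in zone 3 (pericentral), as in the injury model
    z3 = np.flatnonzero(zones == "zone3")
    if n_sig > len(z3):
        zones[rng.choice(np.flatnonzero(zones != "zone3"),
                         size=n_sig - len(z3), replace=False)] = "zone3"
        z3 = np.flatnonzero(zones == "zone3")
    sig[rng.choice(z3, size=n_sig, replace=False)] = True
    barcodes = [f"{species[0].upper()}BC{i:05d}" for i in range(n + cfg.n_outlier_cells)]
    kinds = ["mito", "high_umi", "low_genes"]
    outlier_kind = [kinds[i % 3] for i in range(cfg.n_outlier_cells)]
    truth = pd.DataFrame({
        "barcode": barcodes,
        "zone": list(zones) + ["unassigned"] * cfg.n_outlier_cells,
        "signature": list(sig) + [False] * cfg.n_outlier_cells,
        "outlier": [False] * n + [True] * cfg.n_outlier_cells,
        "outlier_kind": [""] * n + outlier_kind,
    }).set_index("barcode")
    return truth


def _species_counts(cfg, rng, gene_truth, cell_truth, base_means, preset_name,
                    species, symbols):
    """ZINB counts for one species, outlier rows appended last."""
    n_genes = len(base_means)
    roles = gene_truth["role"].to_numpy()
    mito = roles == "mito"
    # rescale mito means so the expected mito UMI fraction hits the target
    means = base_means.copy()
    non_mito_total = means[~mito].sum()
    tgt = cfg.target_mito_fraction
    means[mito] = tgt / (1 - tgt) * non_mito_total / max(mito.sum(), 1)

    normal = ~cell_truth["outlier"].to_numpy()
    n_normal = int(normal.sum())
    zones = cell_truth["zone"].to_numpy()
    sig = cell_truth["signature"].to_numpy()

    mu = np.tile(means, (len(cell_truth), 1))
    for z in ("zone1", "zone2", "zone3"):
        zmask = zones == z
        gmask = roles == f"{z}_marker"
        if zmask.any() and gmask.any():
            mu[np.ix_(zmask, gmask)] *= cfg.zone_marker_fold
    fold = 2.0 ** cfg.signature_log2fc
    mu[np.ix_(sig, roles == "up")] *= fold
    mu[np.ix_(sig, roles == "down")] /= fold

    lib = np.exp(rng.normal(0.0, cfg.libsize_sd, size=len(cell_truth)))
    lib = np.clip(lib, *cfg.libsize_clip)

    preset = _preset(preset_name)
    expected_umi = means.sum()
    kinds = cell_truth["outlier_kind"].to_numpy()
    low_gene_mask = np.zeros((len(cell_truth), n_genes), dtype=bool)
    for i in np.flatnonzero(~normal):
        kind = kinds[i]
        if kind == "mito":
            # inflate mitochondrial means to ~25% of UMI (threshold is 5%)
            mu[i, mito] *= 0.25 / tgt
        elif kind == "high_umi":
            lib[i] = 1.5 * preset.max_umi / expected_umi
        elif kind == "low_genes":
            # restrict expression to a small non-mito subpanel, boosted so
            # the cell is not low-UMI, only low-complexity
            keep = rng.choice(np.flatnonzero(~mito),
                              size=max(preset.min_genes // 4, 10), replace=False)
            mask = np.ones(n_genes, dtype=bool)
            mask[keep] = False
            low_gene_mask[i] = mask
            mu[i, keep] *= 4.0

    mu = mu * lib[:, None]
    x = sample_zinb(mu, cfg.zinb_dispersion, cfg.zinb_dropout, rng=rng)
    x[low_gene_mask] = 0

    var = pd.DataFrame({
        "mito": mito,
        "role": roles,
    }, index=pd.Index(symbols, dtype=str))
    obs = pd.DataFrame(index=cell_truth.index)
    obs["species"] = species
    if species == "mouse":
        obs["tom_label"] = np.where(sig, "Tom+", "Tom-")
    adata = ad.AnnData(X=sp.csr_matrix(x), obs=obs, var=var)
    return adata, n_normal


def make_homology_table(gene_truth: pd.DataFrame, m2m_fraction=0.0,
                        unmapped_fraction=0.0, seed=0) -> pd.DataFrame:
    """Homology table with one shared class key per ortholog group.

    A ``m2m_fraction`` of 1:1 groups is augmented with a second mouse gene
    (drawn from unmapped mouse orphans) to create 2-mouse:1-human groups;
    the remaining orphans stay absent from the table.
    """
    pairs = gene_truth[gene_truth["human_symbol_partner"] != ""]
    if pairs.empty:
        raise ValueError("truth table contains no ortholog partners")
    rng = np.random.default_rng(seed)
    rows = [(m, h, f"KEY:{i:06d}") for i, (m, h) in enumerate(
        zip(pairs["mouse_symbol"], pairs["human_symbol_partner"]))]
    orphans = list(gene_truth.loc[
        (gene_truth["human_symbol_partner"] == "")
        & (gene_truth["role"] != "mito"), "mouse_symbol"])
    n_m2m = min(int(round(m2m_fraction * len(rows))), len(orphans))
    if n_m2m:
        extra_mouse = rng.choice(orphans, size=n_m2m, replace=False)
        group_idx = rng.choice(len(rows), size=n_m2m, replace=False)
        for m, gi in zip(extra_mouse, group_idx):
            _, h, key = rows[gi]
            rows.append((m, h, key))
    table = pd.DataFrame(rows, columns=["mouse_symbol", "human_symbol", "class_key"])
    return table.reset_index(drop=True)


def _embeddings(cfg, rng, gene_truth, human_genes):
    d = cfg.embedding_dim
    mouse_genes = list(gene_truth["mouse_symbol"])
    partner = gene_truth["human_symbol_partner"].to_numpy()
    base = rng.normal(size=(len(mouse_genes), d))
    emb_m = base + rng.normal(0.0, cfg.embedding_noise_sd, size=base.shape)
    emb_h = np.empty((len(human_genes), d))
    h_index = {g: i for i, g in enumerate(human_genes)}
    paired_h = set()
    for i, p in enumerate(partner):
        if p:
            emb_h[h_index[p]] = base[i] + rng.normal(
                0.0, cfg.embedding_noise_sd, size=d)
            paired_h.add(p)
    for g, j in h_index.items():
        if g not in paired_h:
            emb_h[j] = rng.normal(size=d)
    rows = pd.DataFrame(
        np.vstack([emb_m, emb_h]),
        index=mouse_genes + list(human_genes),
        columns=[f"e{k}" for k in range(d)],
    )
    rows.insert(0, "species", ["mouse"] * len(mouse_genes) + ["human"] * len(human_genes))
    rows.index.name = "gene"
    return rows


def simulate_bundle(config: SimConfig) -> SyntheticBundle:
    """Generate the full two-species bundle; reproducible from ``config.seed``."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)

    mouse_genes, human_genes, gene_truth = _gene_panel(cfg, rng)
    base_means = np.exp(rng.normal(cfg.mean_log_mu, cfg.mean_log_sd,
                                   size=cfg.n_genes_per_species))

    truth_m = _cell_truth(cfg, rng, "mouse")
    truth_h = _cell_truth(cfg, rng, "human")
    adata_m, _ = _species_counts(cfg, rng, gene_truth, truth_m, base_means,
                                 cfg.qc_preset_mouse, "mouse", mouse_genes)
    adata_h, _ = _species_counts(cfg, rng, gene_truth, truth_h, base_means,
                                 cfg.qc_preset_human, "human", human_genes)

    homology = make_homology_table(gene_truth, cfg.m2m_fraction,
                                   cfg.unmapped_fraction, seed=cfg.seed + 1)
    embeddings = _embeddings(cfg, rng, gene_truth, human_genes)

    truth = {
        "cells_mouse": truth_m,
        "cells_human": truth_h,
        "genes": gene_truth,
    }
    return SyntheticBundle(adata_m, adata_h, homology, embeddings, truth, cfg)


def write_bundle(bundle: SyntheticBundle, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    xio.write_counts(bundle.counts_mouse, outdir / "mouse")
    xio.write_counts(bundle.counts_human, outdir / "human")
    xio.write_homology_table(bundle.homology, outdir / "homology.tsv")
    xio.write_embeddings(bundle.embeddings, outdir / "embeddings.tsv")
    truth = {
        "cells_mouse": bundle.truth["cells_mouse"].reset_index().to_dict("list"),
        "cells_human": bundle.truth["cells_human"].reset_index().to_dict("list"),
        "genes": bundle.truth["genes"].to_dict("list"),
        "config": dataclasses.asdict(bundle.config) if bundle.config else None,
    }
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(type(o))
    (outdir / "truth.json").write_text(json.dumps(truth, default=_default))
    return outdir
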