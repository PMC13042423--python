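"""Disk formats: MTX count matrices with TSV metadata, GMT gene sets,
homology tables, embeddings and plain gene lists.

A count-matrix directory contains ``matrix.mtx`` (Matrix Market, 1-indexed
coordinates per the format standard), ``cells.tsv`` (row metadata, first
column ``barcode``), ``genes.tsv`` (column metadata, first column ``symbol``
plus a boolean ``mito`` flag) and ``manifest.json`` declaring the matrix
orientation and dimensions. All internal indices are 0-based; conversion
happens only at this boundary (scipy's Matrix Market reader handles it).
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "read_counts", "write_counts", "read_gmt", "write_gmt",
    "read_gene_list", "write_gene_list", "read_homology_table",
    "write_homology_table", "read_embeddings", "write_embeddings",
]


class FormatError(ValueError):
    """Raised when on-disk files are mutually inconsistent."""


def write_counts(adata: ad.AnnData, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = sp.coo_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), x, field="integer")
    cells = adata.obs.copy()
    cells.insert(0, "barcode", adata.obs_names)
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    genes = adata.var.copy()
    genes.insert(0, "symbol", adata.var_names)
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    manifest = {
        "orientation": "cells_by_genes",
        "n_cells": int(adata.n_obs),
        "n_genes": int(adata.n_vars),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def read_counts(path) -> ad.AnnData:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    x = sp.csr_matrix(scipy.io.mmread(str(path / "matrix.mtx")))
    if manifest.get("orientation") == "genes_by_cells":
        x = x.T.tocsr()
    cells = pd.read_csv(path / "cells.tsv", sep="\t", dtype={"barcode": str})
    genes = pd.read_csv(path / "genes.tsv", sep="\t", dtype={"symbol": str})
    if x.shape[0] != len(cells) or x.shape[1] != len(genes):
        raise FormatError(
            f"matrix is {x.shape} but metadata lists {len(cells)} cells and "
            f"{len(genes)} genes")
    if (manifest["n_cells"], manifest["n_genes"]) != x.shape:
        raise FormatError("manifest dimensions disagree with matrix.mtx header")
    if x.nnz and x.data.min() < 0:
        raise FormatError("negative entries in count matrix")
    adata = ad.AnnData(
        X=x.astype(np.int64),
        obs=cells.set_index("barcode"),
        var=genes.set_index("symbol"),
    )
    adata.obs_names.name = None
    adata.var_names.name = None
    return adata


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"malformed GMT line: {line[:80]!r}")
        name, _desc, *genes = parts
        if name in sets:
            raise FormatError(f"duplicate gene-set name {name!r}")
        sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description="na") -> Path:
    path = Path(path)
    lines = ["\t".join([name, description, *genes]) for name, genes in sets.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes, path) -> Path:
    path = Path(path)
    path.write_text("\n".join(genes) + ("\n" if len(genes) else ""))
    return path


def write_homology_table(table: pd.DataFrame, path) -> Path:
    cols = ["mouse_symbol", "human_symbol", "class_key"]
    table[cols].to_csv(path, sep="\t", index=False)
    return Path(path)


def read_homology_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"mouse_symbol", "human_symbol", "class_key"} - set(table.columns)
    if missing:
        raise FormatError(f"homology table missing columns: {sorted(missing)}")
    if table["class_key"].isna().any() or (table["class_key"] == "").any():
        raise FormatError("homology table has empty class keys")
    if table.duplicated().any():
        raise FormatError("homology table has fully duplicated rows")
    return table


def write_embeddings(emb: pd.DataFrame, path) -> Path:
    """``emb``: index = gene symbol, ``species`` column + e0..e{d-1} floats."""
    out = emb.copy()
    out.insert(0, "gene", emb.index)
    out.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_embeddings(path) -> pd.DataFrame:
    emb = pd.read_csv(path, sep="\t")
    emb = emb.set_index("gene")
    dim_cols = [c for c in emb.columns if c.startswith("e")]
    if not dim_cols:
        raise FormatError("embedding table has no e* dimension columns")
    if not np.isfinite(emb[dim_cols].to_numpy(dtype=float)).all():
        raise FormatError("embedding table contains non-finite values")
    return emb
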