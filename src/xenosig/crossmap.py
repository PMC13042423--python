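"""Mouse-to-human gene conversion.

Two routes are provided:

* **Homology-key lookup** — a table of (mouse_symbol, human_symbol,
  class_key) rows; a mouse symbol converts to every human symbol sharing
  its homology class key.
* **Macrogene weight pairing** — genes of both species are embedded in a
  shared "macrogene" space: a nonnegative weight matrix ``W`` (macrogenes x
  genes), initialized from k-means over protein-embedding vectors and
  refined by a ZINB autoencoder (reconstruction loss ``L_rc``) plus a
  supplementary loss ``L_s`` that keeps weight-column cosine similarities
  close to protein-embedding cosine similarities. A mouse gene i and human
  gene j are paired when the cosine similarity of their weight columns
  exceeds a cutoff (default 0.85, strict).

The autoencoder is a linear encoder over per-cell macrogene expression
(``lognorm . W_species^T``) with a species-specific linear decoder head
producing ZINB means, plus per-gene dispersion and dropout parameters. It
is trained with hand-derived analytic gradients and Adam, full-batch by
default at desk scale (smooth, deterministic loss trace); a minibatch size
may be set for larger data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .qc import normalize_log
from .zinb import zinb_nll_and_grad

__all__ = ["convert_symbols_mgi", "init_macrogene_weights", "MacrogeneModel",
           "pretrain", "cosine_similarity", "pair_genes",
           "convert_symbols_saturn"]

_EPS = 1e-8


# ---------------------------------------------------------------- homology

def convert_symbols_mgi(gene_list, table: pd.DataFrame):
    """Convert mouse symbols to human symbols through shared class keys.

    Returns ``(converted, report)`` where ``converted`` is deduplicated in
    order of first appearance and ``report`` lists unmapped inputs and the
    per-input mapping.
    """
    key_of = {}
    humans_of_key = {}
    for m, h, k in zip(table["mouse_symbol"], table["human_symbol"],
                       table["class_key"]):
        key_of.setdefault(m, set()).add(k)
        humans_of_key.setdefault(k, [])
        if h not in humans_of_key[k]:
            humans_of_key[k].append(h)
    converted, seen = [], set()
    mapping, unmapped = {}, []
    for g in gene_list:
        targets = []
        for k in sorted(key_of.get(g, ())):
            targets.extend(humans_of_key[k])
        if not targets:
            unmapped.append(g)
            continue
        mapping[g] = targets
        for t in targets:
            if t not in seen:
                seen.add(t)
                converted.append(t)
    report = {"unmapped": unmapped, "mapping": mapping,
              "n_input": len(gene_list), "n_output": len(converted)}
    return converted, report


# ------------------------------------------------------------- macrogenes

def _softplus(x):
    return np.logaddexp(0.0, x)


def _inv_softplus(y):
    # log(expm1(y)), stable at both ends
    yc = np.clip(y, 1e-12, 20.0)
    return np.where(y > 20, y, np.log(np.expm1(yc)))


def init_macrogene_weights(embeddings: np.ndarray, n_macrogenes: int,
                           seed: int = 0) -> np.ndarray:
    """Initial macrogene weights from k-means over protein embeddings.

    ``W[m, g] = softplus(-dist(e_g, centroid_m))``: nonnegative, larger for
    genes near the centroid, so genes with similar embeddings start with
    similar weight columns.
    """
    from sklearn.cluster import KMeans

    emb = np.asarray(embeddings, dtype=float)
    n_genes = emb.shape[0]
    if n_macrogenes > n_genes:
        raise ValueError("more macrogenes than genes")
    km = KMeans(n_clusters=n_macrogenes, n_init=10, random_state=seed)
    km.fit(emb)
    dist = np.linalg.norm(emb[None, :, :] - km.cluster_centers_[:, None, :],
                          axis=2)                      # (M, genes)
    return _softplus(-dist)


@dataclass
class MacrogeneModel:
    """Trained gene-to-macrogene weights plus autoencoder parameters."""
    W: np.ndarray                      # (M, n_total_genes), nonnegative
    gene_names: list
    species: np.ndarray                # per gene: "mouse" | "human"
    params: dict = field(repr=False, default_factory=dict)
    trace: pd.DataFrame | None = None  # per-step l_rc, l_s, total
    config: dict = field(default_factory=dict)

    def weight_column(self, gene):
        return self.W[:, self.gene_names.index(gene)]

    def save(self, path):
        """Single-file checkpoint (numpy archive) with weights, decoder
        parameters, loss trace and config."""
        import json

        payload = {"W": self.W, "species": self.species,
                   "gene_names": np.asarray(self.gene_names, dtype=object)}
        if self.trace is not None:
            payload["trace"] = self.trace.to_numpy()
            payload["trace_columns"] = np.asarray(self.trace.columns,
                                                  dtype=object)
        for key in ("encoder",):
            if key in self.params:
                payload[key] = self.params[key]
        for key in ("decoder", "bias", "theta", "pi"):
            for s, arr in self.params.get(key, {}).items():
                payload[f"{key}_{s}"] = arr
        payload["config_json"] = np.asarray(json.dumps(self.config))
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path):
        import json

        with np.load(path, allow_pickle=True) as npz:
            params = {}
            if "encoder" in npz:
                params["encoder"] = npz["encoder"]
            for key in ("decoder", "bias", "theta", "pi"):
                sub = {s: npz[f"{key}_{s}"] for s in ("mouse", "human")
                       if f"{key}_{s}" in npz}
                if sub:
                    params[key] = sub
            trace = None
            if "trace" in npz:
                trace = pd.DataFrame(npz["trace"],
                                     columns=list(npz["trace_columns"]))
            return cls(W=npz["W"], gene_names=list(npz["gene_names"]),
                       species=npz["species"], params=params, trace=trace,
                       config=json.loads(str(npz["config_json"])))


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _unit_cols(w):
    norms = np.linalg.norm(w, axis=0)
    return w / np.maximum(norms, _EPS), np.maximum(norms, _EPS)


def _ls_loss_grad(wm, wh, target):
    """Mean squared difference between weight-column cosine similarity and
    embedding cosine similarity, with gradients w.r.t. both weight blocks."""
    um, nm = _unit_cols(wm)
    uh, nh = _unit_cols(wh)
    cos = um.T @ uh                                   # (Gm, Gh)
    diff = cos - target
    loss = float(np.mean(diff ** 2))
    a = 2.0 * diff / diff.size
    # d cos_ij / d wm_i = (uh_j - cos_ij um_i) / ||wm_i||
    g_m = (uh @ a.T - um * (a * cos).sum(axis=1)) / nm
    g_h = (um @ a - uh * (a * cos).sum(axis=0)) / nh
    return loss, g_m, g_h


def pretrain(counts_mouse, counts_human, embeddings, n_macrogenes=50,
             steps=2000, lambda_s=1.0, lr=1e-3, latent_dim=32,
             batch_size=None, seed=0, W_init=None) -> MacrogeneModel:
    """Train the macrogene autoencoder on both species' count matrices.

    ``counts_*`` are AnnData (cells x genes, raw counts); ``embeddings`` a
    DataFrame indexed by gene symbol with a ``species`` column and e*
    dimension columns covering both panels. Genes with all-zero counts are
    excluded before training (their ZINB fit is unidentifiable).

    The recorded trace holds, per step, the full-data reconstruction loss
    ``l_rc`` (mean ZINB NLL per matrix entry), the supplementary loss
    ``l_s`` and ``total = l_rc + lambda_s * l_s``.
    """
    rng = np.random.default_rng(seed)

    def _prep(adata):
        x = sp.csr_matrix(adata.X)
        keep = np.asarray(x.sum(axis=0)).ravel() > 0
        genes = [g for g, k in zip(adata.var_names, keep) if k]
        raw = np.asarray(x[:, keep].todense(), dtype=float)
        logn = np.asarray(normalize_log(x[:, keep]).todense())
        return raw, logn, genes

    raw_m, log_m, genes_m = _prep(counts_mouse)
    raw_h, log_h, genes_h = _prep(counts_human)
    if set(genes_m) & set(genes_h):
        raise ValueError("species count matrices must not share gene symbols")

    dim_cols = [c for c in embeddings.columns if c.startswith("e")]
    emb_m = embeddings.loc[genes_m, dim_cols].to_numpy(dtype=float)
    emb_h = embeddings.loc[genes_h, dim_cols].to_numpy(dtype=float)
    emb_all = np.vstack([emb_m, emb_h])

    gm, gh = len(genes_m), len(genes_h)
    m = n_macrogenes
    if W_init is None:
        W_init = init_macrogene_weights(emb_all, m, seed=seed)
    w_raw = _inv_softplus(np.maximum(W_init, 1e-6))

    # embedding-similarity target for L_s (cross-species block)
    um = emb_m / np.maximum(np.linalg.norm(emb_m, axis=1, keepdims=True), _EPS)
    uh = emb_h / np.maximum(np.linalg.norm(emb_h, axis=1, keepdims=True), _EPS)
    target = um @ uh.T                                  # (Gm, Gh)

    scale = 0.1
    enc = rng.normal(scale=scale, size=(m, latent_dim))
    dec = {"mouse": rng.normal(scale=scale, size=(latent_dim, gm)),
           "human": rng.normal(scale=scale, size=(latent_dim, gh))}
    bias = {"mouse": np.zeros(gm), "human": np.zeros(gh)}
    theta_raw = {"mouse": np.zeros(gm), "human": np.zeros(gh)}
    pi_raw = {"mouse": np.full(gm, -2.0), "human": np.full(gh, -2.0)}

    cols = {"mouse": slice(0, gm), "human": slice(gm, gm + gh)}
    data = {"mouse": (raw_m, log_m), "human": (raw_h, log_h)}
    from scipy.special import gammaln
    lgamma_cache = {s: gammaln(data[s][0] + 1.0) for s in data}

    params = [w_raw, enc, dec["mouse"], dec["human"], bias["mouse"],
              bias["human"], theta_raw["mouse"], theta_raw["human"],
              pi_raw["mouse"], pi_raw["human"]]
    opt = _Adam([p.shape for p in params], lr)

    def forward(species, rows=None):
        raw, logn = data[species]
        if rows is not None:
            raw, logn = raw[rows], logn[rows]
        w = _softplus(w_raw[:, cols[species]])
        c = logn @ w.T                                   # (n, M)
        z = c @ enc                                      # (n, L)
        a = z @ dec[species] + bias[species]
        mu = _softplus(a) + 1e-6
        theta = _softplus(theta_raw[species]) + 1e-4
        pi = 1.0 / (1.0 + np.exp(-pi_raw[species]))
        pi = np.clip(pi, 0.0, 1.0 - 1e-6)
        return raw, logn, w, c, z, a, mu, theta, pi

    trace = {"l_rc": [], "l_s": [], "total": []}
    for step in range(steps):
        grads = [np.zeros_like(p) for p in params]
        l_rc_acc, n_entries = 0.0, 0
        for si, s in enumerate(("mouse", "human")):
            n_cells = data[s][0].shape[0]
            rows = None
            if batch_size is not None and batch_size < n_cells:
                rows = rng.choice(n_cells, size=batch_size, replace=False)
            raw, logn, w, c, z, a, mu, theta, pi = forward(s, rows)
            n_b = raw.size
            cache = lgamma_cache[s] if rows is None else None
            nll, d_mu, d_theta, d_pi = zinb_nll_and_grad(
                raw, mu, theta[None, :], pi[None, :], lgamma_x1=cache)
            l_rc_acc += nll
            n_entries += n_b
            # normalize per entry so losses are comparable across scales
            d_mu = d_mu / n_b
            da = d_mu * (1.0 / (1.0 + np.exp(-a)))      # softplus'
            g_dec = z.T @ da
            g_bias = da.sum(axis=0)
            dz = da @ dec[s].T
            g_enc_s = c.T @ dz
            dc = dz @ enc.T
            g_w = dc.T @ logn                            # (M, G_s)
            sig_w = 1.0 / (1.0 + np.exp(-w_raw[:, cols[s]]))
            grads[0][:, cols[s]] += g_w * sig_w
            grads[1] += g_enc_s
            grads[2 + si] += g_dec
            grads[4 + si] += g_bias
            th_sig = 1.0 / (1.0 + np.exp(-theta_raw[s]))
            grads[6 + si] += d_theta.sum(axis=0) / n_b * th_sig
            grads[8 + si] += d_pi.sum(axis=0) / n_b * pi * (1 - pi)
        l_rc = l_rc_acc / n_entries

        w_full = _softplus(w_raw)
        l_s, g_wm, g_wh = _ls_loss_grad(w_full[:, cols["mouse"]],
                                        w_full[:, cols["human"]], target)
        sig_full = 1.0 / (1.0 + np.exp(-w_raw))
        grads[0][:, cols["mouse"]] += lambda_s * g_wm * sig_full[:, cols["mouse"]]
        grads[0][:, cols["human"]] += lambda_s * g_wh * sig_full[:, cols["human"]]

        total = l_rc + lambda_s * l_s
        if not np.isfinite(total):
            raise FloatingPointError(f"training diverged at step {step}")
        trace["l_rc"].append(l_rc)
        trace["l_s"].append(l_s)
        trace["total"].append(total)
        opt.step(params, grads)

    model = MacrogeneModel(
        W=_softplus(w_raw),
        gene_names=genes_m + genes_h,
        species=np.array(["mouse"] * gm + ["human"] * gh),
        params={
            "encoder": enc, "decoder": dec, "bias": bias,
            "theta": {s: _softplus(theta_raw[s]) + 1e-4 for s in theta_raw},
            "pi": {s: 1.0 / (1.0 + np.exp(-pi_raw[s])) for s in pi_raw},
        },
        trace=pd.DataFrame(trace),
        config={"n_macrogenes": m, "steps": steps, "lambda_s": lambda_s,
                "lr": lr, "latent_dim": latent_dim,
                "batch_size": batch_size, "seed": seed},
    )
    return model


def cosine_similarity(w_i, w_j) -> float:
    """Cosine similarity of two weight vectors; errors on zero vectors."""
    w_i = np.asarray(w_i, dtype=float)
    w_j = np.asarray(w_j, dtype=float)
    ni = np.linalg.norm(w_i)
    nj = np.linalg.norm(w_j)
    if ni == 0 or nj == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(w_i, w_j) / (ni * nj))


def pair_genes(model: MacrogeneModel, threshold=0.85) -> pd.DataFrame:
    """All cross-species gene pairs whose weight-column cosine similarity
    strictly exceeds ``threshold``, sorted by similarity descending."""
    is_m = model.species == "mouse"
    wm = model.W[:, is_m]
    wh = model.W[:, ~is_m]
    um, _ = _unit_cols(wm)
    uh, _ = _unit_cols(wh)
    sims = um.T @ uh
    names = np.asarray(model.gene_names, dtype=object)
    mi, hj = np.nonzero(sims > threshold)
    pairs = pd.DataFrame({
        "mouse_symbol": names[is_m][mi],
        "human_symbol": names[~is_m][hj],
        "similarity": sims[mi, hj],
    }).sort_values("similarity", ascending=False, kind="stable")
    return pairs.reset_index(drop=True)


def cross_species_similarity(model: MacrogeneModel) -> pd.DataFrame:
    """Full mouse x human similarity matrix (rows: mouse symbols)."""
    is_m = model.species == "mouse"
    um, _ = _unit_cols(model.W[:, is_m])
    uh, _ = _unit_cols(model.W[:, ~is_m])
    names = np.asarray(model.gene_names, dtype=object)
    return pd.DataFrame(um.T @ uh, index=names[is_m], columns=names[~is_m])


def convert_symbols_saturn(gene_list, pairs: pd.DataFrame):
    """Convert mouse symbols through macrogene-similarity gene pairs.

    Same dedup/reporting contract as :func:`convert_symbols_mgi`; genes
    with no pair above threshold are dropped and reported.
    """
    mapping_of = {}
    for m, h in zip(pairs["mouse_symbol"], pairs["human_symbol"]):
        mapping_of.setdefault(m, [])
        if h not in mapping_of[m]:
            mapping_of[m].append(h)
    converted, seen = [], set()
    mapping, unmapped = {}, []
    for g in gene_list:
        targets = mapping_of.get(g, [])
        if not targets:
            unmapped.append(g)
            continue
        mapping[g] = targets
        for t in targets:
            if t not in seen:
                seen.add(t)
                converted.append(t)
    report = {"unmapped": unmapped, "mapping": mapping,
              "n_input": len(gene_list), "n_output": len(converted)}
    return converted, report
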