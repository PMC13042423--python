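"""End-to-end driver: simulate -> QC -> zones -> clustering -> DEG ->
cross-species conversion (homology table and macrogene pairing) -> Tom
scores, with a machine-readable run report.

Every stage writes to its own subdirectory of the run output directory and
never mutates its inputs; the report records parameters, cell/gene counts
before and after each filter, warnings, wall time and a sha256 checksum of
every written file, so two runs with the same config and seed can be
compared checksum-by-checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import crossmap, io as xio, qc as qcmod, tomscore as tsmod
from .deg import differential_expression
from .gsva import GsvaParams, gsva_scores
from .simdata import SimConfig, simulate_bundle, write_bundle

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    seed: int = 0
    sim: dict = field(default_factory=dict)
    qc_preset_mouse: str = "mouse_hepatocyte"
    qc_preset_human: str = "human_hepatocyte"
    cluster: dict = field(default_factory=lambda: {
        "n_hvg": 2000, "n_pcs": 20, "n_clusters": 8, "method": "kmeans"})
    deg: dict = field(default_factory=lambda: {
        "groupby": "tom_label", "group_a": "Tom+", "group_b": "Tom-",
        "lfc_threshold": 0.3, "alpha": 0.05, "min_frac": 0.10})
    # conversion route: ~2 genes per macrogene keeps pairing precise at the
    # 0.85 cosine cutoff; quality saturates within a few hundred steps here
    crossmap: dict = field(default_factory=lambda: {
        "panel_size": 400, "n_macrogenes": 400, "steps": 300,
        "lambda_s": 1.0, "lr": 1e-3, "threshold": 0.85})
    gsva: dict = field(default_factory=lambda: {
        "kcdf": "gaussian", "tau": 1.0, "score_mode": "max_diff"})
    contaminant_marker_fold: float = 3.0

    def __post_init__(self):
        # user-supplied section dicts override defaults key-by-key
        for section in ("cluster", "deg", "crossmap", "gsva"):
            defaults = RunConfig.__dataclass_fields__[section].default_factory()
            merged = {**defaults, **getattr(self, section)}
            setattr(self, section, merged)

    _KNOWN_SUBKEYS = {
        "cluster": {"n_hvg", "n_pcs", "n_clusters", "method"},
        "deg": {"groupby", "group_a", "group_b", "lfc_threshold", "alpha",
                "min_frac"},
        "crossmap": {"panel_size", "n_macrogenes", "steps", "lambda_s", "lr",
                     "threshold", "batch_size", "latent_dim"},
        "gsva": {"kcdf", "tau", "score_mode", "min_set_size", "max_set_size"},
    }

    def validate(self):
        problems = []
        try:
            SimConfig(seed=self.seed, **self.sim).validate()
        except (TypeError, ValueError) as e:
            problems.append(f"sim: {e}")
        for attr in ("qc_preset_mouse", "qc_preset_human"):
            if getattr(self, attr) not in qcmod.PRESETS:
                problems.append(f"{attr}: unknown preset {getattr(self, attr)!r}")
        for section, known in self._KNOWN_SUBKEYS.items():
            unknown = set(getattr(self, section)) - known
            if unknown:
                problems.append(f"{section}: unknown keys {sorted(unknown)}")
        try:
            GsvaParams(**self.gsva).validate()
        except (TypeError, ValueError) as e:
            problems.append(f"gsva: {e}")
        if self.cluster.get("n_pcs", 20) < 1:
            problems.append("cluster: n_pcs must be >= 1")
        if problems:
            raise ValueError("invalid run config:\n  " + "\n  ".join(problems))
        return self


def load_config(path) -> RunConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)
    status: str = "ok"
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {"status": self.status, "failed_stage": self.failed_stage,
             "config": self.config, "stages": self.stages},
            indent=1, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _checksums(stage_dir: Path) -> dict:
    return {p.name: _sha256(p) for p in sorted(stage_dir.rglob("*"))
            if p.is_file()}


def run_pipeline(config: RunConfig, outdir) -> RunReport:
    """Execute all stages; raises on stage failure after writing the
    partial report to ``outdir/report.json``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config))
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("qc", _stage_qc),
        ("cluster", _stage_cluster),
        ("zones", _stage_zones),
        ("deg", _stage_deg),
        ("crossmap", _stage_crossmap),
        ("tomscore", _stage_tomscore),
    ]
    try:
        for name, fn in stages:
            stage_dir = outdir / name
            stage_dir.mkdir(exist_ok=True)
            t0 = time.perf_counter()
            info = fn(config, state, stage_dir)
            info["wall_time_s"] = round(time.perf_counter() - t0, 3)
            info["outputs"] = _checksums(stage_dir)
            report.stages[name] = info
    except Exception as e:
        report.status = "failed"
        report.failed_stage = name
        report.stages[name] = {"error": str(e)}
        (outdir / "report.json").write_text(report.to_json())
        raise
    (outdir / "report.json").write_text(report.to_json())
    return report


def _stage_simulate(cfg: RunConfig, state, stage_dir):
    sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim)
    bundle = simulate_bundle(sim_cfg)
    write_bundle(bundle, stage_dir)
    state["bundle"] = bundle
    return {"n_cells_mouse": int(bundle.counts_mouse.n_obs),
            "n_cells_human": int(bundle.counts_human.n_obs),
            "n_genes_per_species": int(bundle.counts_mouse.n_vars)}


def _stage_qc(cfg: RunConfig, state, stage_dir):
    bundle = state["bundle"]
    info = {}
    for species, adata, preset in (
            ("mouse", bundle.counts_mouse, cfg.qc_preset_mouse),
            ("human", bundle.counts_human, cfg.qc_preset_human)):
        table = qcmod.compute_cell_qc(adata)
        keep, reasons = qcmod.apply_qc_filter(table, preset)
        table.to_csv(stage_dir / f"{species}_qc.tsv", sep="\t")
        out = reasons.copy()
        out.insert(0, "keep", keep)
        out.to_csv(stage_dir / f"{species}_keep.tsv", sep="\t")
        state[f"kept_{species}"] = adata[keep].copy()
        state[f"qc_{species}"] = table
        info[f"{species}_cells_in"] = int(adata.n_obs)
        info[f"{species}_cells_kept"] = int(keep.sum())
        info[f"{species}_preset"] = preset
    return info


def _stage_cluster(cfg: RunConfig, state, stage_dir):
    info = {}
    warnings: list[str] = []
    for species in ("mouse", "human"):
        adata = state[f"kept_{species}"]
        logn = qcmod.normalize_log(adata.X)
        labels = qcmod.cluster_cells(
            logn, n_hvg=cfg.cluster["n_hvg"], n_pcs=cfg.cluster["n_pcs"],
            method=cfg.cluster.get("method", "kmeans"),
            n_clusters=cfg.cluster["n_clusters"], seed=cfg.seed)
        markers = (qcmod.CONTAMINANT_MARKERS_MOUSE if species == "mouse"
                   else qcmod.CONTAMINANT_MARKERS_HUMAN)
        detected = state[f"qc_{species}"].loc[adata.obs_names, "detected_genes"]
        hep_mask = qcmod.exclude_contaminant_clusters(
            logn, adata.var_names, labels, markers,
            detected_genes=detected.to_numpy(),
            marker_fold=cfg.contaminant_marker_fold, warn=warnings.append)
        pd.DataFrame({"cluster": labels, "hepatocyte": hep_mask},
                     index=adata.obs_names).to_csv(
            stage_dir / f"{species}_clusters.tsv", sep="\t")
        state[f"hep_{species}"] = adata[hep_mask].copy()
        state[f"clusters_{species}"] = labels[hep_mask]
        state[f"lognorm_{species}"] = qcmod.normalize_log(
            state[f"hep_{species}"].X)
        info[f"{species}_cells_in"] = int(adata.n_obs)
        info[f"{species}_cells_kept"] = int(hep_mask.sum())
        info[f"{species}_n_clusters"] = int(len(np.unique(labels)))
    info["warnings"] = warnings
    return info


def _stage_zones(cfg: RunConfig, state, stage_dir):
    info = {}
    for species, markers in (("mouse", qcmod.ZONE_MARKERS_MOUSE),
                             ("human", qcmod.ZONE_MARKERS_HUMAN)):
        adata = state[f"hep_{species}"]
        zones = qcmod.assign_zones(state[f"lognorm_{species}"],
                                   adata.var_names, markers)
        zones.to_csv(stage_dir / f"{species}_zones.tsv", sep="\t")
        state[f"zones_{species}"] = zones
        counts = zones["zone"].value_counts().to_dict()
        info[f"{species}_zone_counts"] = {k: int(v) for k, v in counts.items()}
        info[f"{species}_cells_in"] = int(adata.n_obs)
    return info


def _stage_deg(cfg: RunConfig, state, stage_dir):
    adata = state["hep_mouse"]
    col = cfg.deg["groupby"]
    if col not in adata.obs.columns:
        raise ValueError(f"mouse cell metadata lacks column {col!r}")
    groups = adata.obs[col].to_numpy()
    mask_a = groups == cfg.deg["group_a"]
    mask_b = groups == cfg.deg["group_b"]
    sig = differential_expression(
        state["lognorm_mouse"], adata.var_names, mask_a, mask_b,
        lfc_threshold=cfg.deg["lfc_threshold"], alpha=cfg.deg["alpha"],
        min_frac=cfg.deg["min_frac"])
    sig.table.to_csv(stage_dir / "deg_table.tsv", sep="\t")
    xio.write_gene_list(sig.up, stage_dir / "up_genes.txt")
    xio.write_gene_list(sig.down, stage_dir / "down_genes.txt")
    xio.write_gmt({"signature_up": sig.up, "signature_down": sig.down},
                  stage_dir / "signature.gmt")
    state["signature"] = sig
    return {"cells_group_a": int(mask_a.sum()),
            "cells_group_b": int(mask_b.sum()),
            "genes_tested": int(len(sig.table)),
            "n_up": len(sig.up), "n_down": len(sig.down)}


def _stage_crossmap(cfg: RunConfig, state, stage_dir):
    bundle = state["bundle"]
    sig = state["signature"]
    warnings: list[str] = []

    up_mgi, down_mgi, rep = tsmod.transfer_signature(
        sig, "mgi", homology=bundle.homology)
    state["lists_mgi"] = (up_mgi, down_mgi)
    xio.write_gene_list(up_mgi, stage_dir / "up_mgi.txt")
    xio.write_gene_list(down_mgi, stage_dir / "down_mgi.txt")

    # macrogene route: train on the top dispersion panel of each species
    panel = int(cfg.crossmap["panel_size"])
    sub = {}
    for species in ("mouse", "human"):
        adata = state[f"hep_{species}"]
        hvg = qcmod.select_hvg(state[f"lognorm_{species}"], panel)
        sub[species] = adata[:, hvg].copy()
    model = crossmap.pretrain(
        sub["mouse"], sub["human"], bundle.embeddings,
        n_macrogenes=int(cfg.crossmap["n_macrogenes"]),
        steps=int(cfg.crossmap["steps"]),
        lambda_s=float(cfg.crossmap["lambda_s"]),
        lr=float(cfg.crossmap["lr"]),
        batch_size=cfg.crossmap.get("batch_size"),
        latent_dim=int(cfg.crossmap.get("latent_dim", 32)),
        seed=cfg.seed)
    model.trace.to_csv(stage_dir / "training_trace.tsv", sep="\t",
                       index_label="step")
    pairs = crossmap.pair_genes(model, threshold=float(cfg.crossmap["threshold"]))
    pairs.to_csv(stage_dir / "gene_pairs.tsv", sep="\t", index=False)
    up_sat, down_sat, rep_s = tsmod.transfer_signature(sig, "saturn", pairs=pairs)
    state["lists_saturn"] = (up_sat, down_sat)
    state["macrogene_model"] = model
    xio.write_gene_list(up_sat, stage_dir / "up_saturn.txt")
    xio.write_gene_list(down_sat, stage_dir / "down_saturn.txt")
    for name, r in (("mgi", rep), ("saturn", rep_s)):
        for direction in ("up", "down"):
            n_un = len(r[direction]["unmapped"])
            if n_un:
                warnings.append(f"{name} {direction}: {n_un} unmapped symbols")
    return {
        "mgi_up": len(up_mgi), "mgi_down": len(down_mgi),
        "saturn_up": len(up_sat), "saturn_down": len(down_sat),
        "n_gene_pairs": int(len(pairs)),
        "final_loss": float(model.trace["total"].iloc[-1]),
        "initial_loss": float(model.trace["total"].iloc[0]),
        "warnings": warnings,
    }


def _stage_tomscore(cfg: RunConfig, state, stage_dir):
    adata = state["hep_human"]
    expr = np.asarray(state["lognorm_human"].todense()).T   # genes x cells
    sets = {}
    for method in ("mgi", "saturn"):
        up, down = state[f"lists_{method}"]
        sets[f"up_{method}"] = up
        sets[f"down_{method}"] = down
    params = GsvaParams(**cfg.gsva)
    res = gsva_scores(expr, adata.var_names, sets, params=params,
                      sample_names=adata.obs_names)
    info = {}
    for method in ("mgi", "saturn"):
        for direction in ("up", "down"):
            key = f"{direction}_{method}"
            if key in res.errors:
                raise ValueError(f"GSVA set {key}: {res.errors[key]}")
        up_s = res.scores.loc[f"up_{method}"].to_numpy()
        down_s = res.scores.loc[f"down_{method}"].to_numpy()
        tom = up_s - down_s
        cells = pd.DataFrame({
            "gsva_up": up_s, "gsva_down": down_s, "tom": tom,
            "group": tsmod.classify_groups(tom),
            "cluster": state["clusters_human"],
        }, index=adata.obs_names)
        r = float(np.corrcoef(up_s, down_s)[0, 1])
        result = tsmod.TomScoreResult(cells=cells.drop(columns="cluster"),
                                      method=method, pearson_r=r, gsva=res)
        summary = tsmod.summarize_by_cluster(result, state["clusters_human"])
        cells.to_csv(stage_dir / f"tom_cells_{method}.tsv", sep="\t")
        summary.to_csv(stage_dir / f"tom_clusters_{method}.tsv", sep="\t")
        state[f"tom_{method}"] = result
        info[f"{method}_pearson_r"] = r
        info[f"{method}_top_cluster"] = int(summary.index[0])
    info["n_cells_scored"] = int(adata.n_obs)
    return info
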