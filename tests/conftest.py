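import numpy as np
import pytest

from xenosig.crossmap import pretrain
from xenosig.simdata import SimConfig, simulate_bundle

DESK_SEED = 11


def desk_config(**overrides):
    """Desk-scale crossmap study conditions: 600 cells and 400 genes per
    species, 300 ortholog pairs, a 10% signature population at log2FC 1.5."""
    base = dict(seed=DESK_SEED, n_cells_per_species=600,
                n_genes_per_species=400, n_ortholog_pairs=300,
                n_up_genes=40, n_down_genes=40, n_outlier_cells=0)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def desk_bundle():
    return simulate_bundle(desk_config())


@pytest.fixture(scope="session")
def trained_model(desk_bundle):
    """Macrogene model pretrained for the reference 2000 steps on the desk
    bundle; shared by the trainer-sanity, ortholog-recovery and Tom-score
    checks."""
    return pretrain(desk_bundle.counts_mouse, desk_bundle.counts_human,
                    desk_bundle.embeddings, n_macrogenes=50, steps=2000,
                    seed=7)


@pytest.fixture(scope="session")
def conversion_model(desk_bundle):
    """Finer macrogene resolution (2 genes per macrogene) used for the
    symbol-conversion route, where pairing precision at the 0.85 cosine
    cutoff matters more than autoencoder convergence."""
    return pretrain(desk_bundle.counts_mouse, desk_bundle.counts_human,
                    desk_bundle.embeddings, n_macrogenes=400, steps=300,
                    seed=7)


@pytest.fixture(scope="session")
def qc_bundle():
    """QC-scale bundle: 1000 cells per species with 15 planted outliers."""
    return simulate_bundle(SimConfig(seed=5, n_cells_per_species=1000,
                                     n_genes_per_species=3500,
                                     n_outlier_cells=15))


def auroc(labels, scores):
    """Rank-based AUROC (Mann-Whitney identity); avoids depending on the
    implementation under test."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    from scipy.stats import rankdata
    r = rankdata(scores)
    n1 = labels.sum()
    n0 = len(labels) - n1
    return (r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
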