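import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xenosig.crossmap import (convert_symbols_mgi, convert_symbols_saturn,
                              cosine_similarity, cross_species_similarity,
                              init_macrogene_weights, pair_genes, pretrain)
from xenosig.simdata import simulate_bundle

from conftest import desk_config


def _table(rows):
    return pd.DataFrame(rows, columns=["mouse_symbol", "human_symbol",
                                       "class_key"])


class TestMgiConversion:
    def test_one_to_one(self):
        t = _table([("Glul", "GLUL", "K1")])
        out, rep = convert_symbols_mgi(["Glul"], t)
        assert out == ["GLUL"] and rep["unmapped"] == []

    def test_many_to_one_deduplicates(self):
        t = _table([("Gene1a", "GENE1", "K1"), ("Gene1b", "GENE1", "K1")])
        out, _ = convert_symbols_mgi(["Gene1a", "Gene1b"], t)
        assert out == ["GENE1"]

    def test_unmapped_reported(self):
        t = _table([("Glul", "GLUL", "K1")])
        out, rep = convert_symbols_mgi(["Nope"], t)
        assert out == [] and rep["unmapped"] == ["Nope"]

    def test_matches_join_oracle(self, desk_bundle):
        table = desk_bundle.homology
        genes = list(table["mouse_symbol"].sample(60, random_state=0))
        out, _ = convert_symbols_mgi(genes, table)
        joined = (pd.DataFrame({"mouse_symbol": genes})
                  .merge(table[["mouse_symbol", "class_key"]])
                  .merge(table[["class_key", "human_symbol"]]))
        assert set(out) == set(joined["human_symbol"])


class TestCosine:
    def test_identity_orthogonality(self):
        assert cosine_similarity([1, 0], [1, 0]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_arithmetic_example(self):
        # 32 / sqrt(14 * 77)
        assert cosine_similarity([1, 2, 3], [4, 5, 6]) == pytest.approx(
            32 / np.sqrt(14 * 77), abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 1])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_brute_force_symmetry_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=6)
        w = rng.normal(size=6)
        brute = float(sum(a * b for a, b in zip(v, w))
                      / (sum(a * a for a in v) ** 0.5
                         * sum(b * b for b in w) ** 0.5))
        got = cosine_similarity(v, w)
        assert got == pytest.approx(brute, abs=1e-12)
        assert got == pytest.approx(cosine_similarity(w, v), abs=1e-15)
        assert got == pytest.approx(cosine_similarity(3.7 * v, w), abs=1e-12)


class TestInitWeights:
    def test_identical_embeddings_identical_columns(self):
        emb = np.vstack([np.ones(4), np.ones(4), np.zeros(4)])
        w = init_macrogene_weights(emb, 2, seed=0)
        np.testing.assert_allclose(w[:, 0], w[:, 1])

    def test_own_centroid_dominates_when_m_equals_genes(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(5, 3)) * 5
        w = init_macrogene_weights(emb, 5, seed=0)
        for g in range(5):
            assert w[np.argmax(w[:, g]), g] == w[:, g].max()
        # every gene's largest weight sits on its own (nearest) centroid
        assert len(set(np.argmax(w, axis=0))) == 5

    def test_cluster_structure_reflected_in_columns(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.05, size=(6, 8)) + np.r_[np.ones(4), np.zeros(4)]
        b = rng.normal(0, 0.05, size=(6, 8)) + np.r_[np.zeros(4), np.ones(4)]
        emb = np.vstack([a, b])
        w = init_macrogene_weights(emb, 2, seed=0)
        unit = w / np.linalg.norm(w, axis=0)
        cos = unit.T @ unit
        within = [cos[i, j] for i in range(6) for j in range(6) if i < j]
        within += [cos[i, j] for i in range(6, 12) for j in range(6, 12) if i < j]
        between = [cos[i, j] for i in range(6) for j in range(6, 12)]
        assert min(within) > max(between)

    def test_too_many_macrogenes_rejected(self):
        with pytest.raises(ValueError):
            init_macrogene_weights(np.ones((3, 2)), 4)


@pytest.fixture(scope="module")
def tiny_bundle():
    return simulate_bundle(desk_config(
        seed=21, n_cells_per_species=80, n_genes_per_species=120,
        n_ortholog_pairs=100, n_up_genes=10, n_down_genes=10))


class TestPretrain:
    def test_loss_decreases_and_reproducible(self, tiny_bundle):
        kwargs = dict(n_macrogenes=12, steps=40, seed=3)
        m1 = pretrain(tiny_bundle.counts_mouse, tiny_bundle.counts_human,
                      tiny_bundle.embeddings, **kwargs)
        m2 = pretrain(tiny_bundle.counts_mouse, tiny_bundle.counts_human,
                      tiny_bundle.embeddings, **kwargs)
        assert m1.trace["total"].iloc[-1] < m1.trace["total"].iloc[0]
        np.testing.assert_array_equal(m1.W, m2.W)
        assert len(m1.trace) == 40

    def test_lambda_zero_total_is_pure_reconstruction(self, tiny_bundle):
        m = pretrain(tiny_bundle.counts_mouse, tiny_bundle.counts_human,
                     tiny_bundle.embeddings, n_macrogenes=12, steps=5,
                     lambda_s=0.0, seed=0)
        np.testing.assert_allclose(m.trace["total"], m.trace["l_rc"])

    def test_shared_symbols_rejected(self, tiny_bundle):
        with pytest.raises(ValueError, match="share"):
            pretrain(tiny_bundle.counts_mouse, tiny_bundle.counts_mouse,
                     tiny_bundle.embeddings, n_macrogenes=5, steps=1)

    def test_checkpoint_round_trip(self, tiny_bundle, tmp_path):
        from xenosig.crossmap import MacrogeneModel
        m = pretrain(tiny_bundle.counts_mouse, tiny_bundle.counts_human,
                     tiny_bundle.embeddings, n_macrogenes=8, steps=5, seed=2)
        m.save(tmp_path / "model.npz")
        back = MacrogeneModel.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(m.W, back.W)
        assert back.gene_names == m.gene_names
        assert back.config == m.config
        np.testing.assert_allclose(m.trace.to_numpy(), back.trace.to_numpy())
        pd.testing.assert_frame_equal(pair_genes(m, 0.9),
                                      pair_genes(back, 0.9))

    def test_minibatch_mode_runs(self, tiny_bundle):
        m = pretrain(tiny_bundle.counts_mouse, tiny_bundle.counts_human,
                     tiny_bundle.embeddings, n_macrogenes=8, steps=10,
                     batch_size=32, seed=1)
        assert np.isfinite(m.trace["total"]).all()


class TestPairing:
    def test_threshold_extremes(self, tiny_bundle):
        m = pretrain(tiny_bundle.counts_mouse, tiny_bundle.counts_human,
                     tiny_bundle.embeddings, n_macrogenes=12, steps=5, seed=0)
        n_mouse = (m.species == "mouse").sum()
        n_human = (m.species == "human").sum()
        everything = pair_genes(m, threshold=-1.0)
        assert len(everything) == n_mouse * n_human
        assert pair_genes(m, threshold=1.0).empty

    def test_pairs_sorted_and_strict(self, tiny_bundle):
        m = pretrain(tiny_bundle.counts_mouse, tiny_bundle.counts_human,
                     tiny_bundle.embeddings, n_macrogenes=12, steps=5, seed=0)
        pairs = pair_genes(m, threshold=0.9)
        assert (pairs["similarity"] > 0.9).all()
        assert (pairs["similarity"].diff().dropna() <= 1e-15).all()

    def test_column_permutation_invariance(self, tiny_bundle):
        m = pretrain(tiny_bundle.counts_mouse, tiny_bundle.counts_human,
                     tiny_bundle.embeddings, n_macrogenes=12, steps=5, seed=0)
        pairs = pair_genes(m, threshold=0.85)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.W.shape[1])
        from xenosig.crossmap import MacrogeneModel
        m2 = MacrogeneModel(W=m.W[:, perm],
                            gene_names=[m.gene_names[i] for i in perm],
                            species=m.species[perm])
        pairs2 = pair_genes(m2, threshold=0.85)
        key = ["mouse_symbol", "human_symbol"]
        assert (set(map(tuple, pairs[key].to_numpy()))
                == set(map(tuple, pairs2[key].to_numpy())))


class TestSaturnConversion:
    def _pairs(self):
        return pd.DataFrame({
            "mouse_symbol": ["Glul", "Glul", "Sds"],
            "human_symbol": ["GLUL", "GLUL2", "SDS"],
            "similarity": [0.99, 0.9, 0.95],
        })

    def test_multi_target_emitted(self):
        out, _ = convert_symbols_saturn(["Glul"], self._pairs())
        assert out == ["GLUL", "GLUL2"]

    def test_unpaired_dropped_and_reported(self):
        out, rep = convert_symbols_saturn(["Hamp"], self._pairs())
        assert out == [] and rep["unmapped"] == ["Hamp"]
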