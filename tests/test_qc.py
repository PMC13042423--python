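import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData
from hypothesis import given, settings
from hypothesis import strategies as st

from xenosig import qc as q


def _adata(x, mito=None):
    x = np.asarray(x)
    n, g = x.shape
    var = pd.DataFrame({"mito": mito if mito is not None else [False] * g},
                       index=[f"g{i}" for i in range(g)])
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    return AnnData(X=sp.csr_matrix(x), obs=obs, var=var)


class TestCellQc:
    def test_arithmetic_example(self):
        # counts [3, 0, 2] with gene2 mitochondrial
        ad = _adata([[3, 0, 2]], mito=[False, False, True])
        t = q.compute_cell_qc(ad)
        assert t.loc["c0", "detected_genes"] == 2
        assert t.loc["c0", "total_umi"] == 5
        assert t.loc["c0", "mito_fraction"] == pytest.approx(0.4)

    def test_all_zero_cell(self):
        t = q.compute_cell_qc(_adata([[0, 0, 0]]))
        assert t.iloc[0].tolist() == [0, 0, 0.0]

    def test_matches_dense_recomputation(self, qc_bundle):
        ad = qc_bundle.counts_mouse
        t = q.compute_cell_qc(ad)
        dense = np.asarray(ad.X.todense(), dtype=float)
        mito = ad.var["mito"].to_numpy()
        assert (t["detected_genes"].to_numpy() == (dense > 0).sum(1)).all()
        assert (t["total_umi"].to_numpy() == dense.sum(1)).all()
        tot = dense.sum(1)
        expect = np.where(tot > 0, dense[:, mito].sum(1) / np.maximum(tot, 1), 0)
        np.testing.assert_allclose(t["mito_fraction"].to_numpy(), expect)

    def test_missing_mito_flag_raises(self):
        ad = _adata([[1]])
        ad.var = ad.var.drop(columns="mito")
        with pytest.raises(ValueError, match="mito"):
            q.compute_cell_qc(ad)


class TestQcFilter:
    def _table(self, detected, umi, mito):
        return pd.DataFrame({"detected_genes": detected, "total_umi": umi,
                             "mito_fraction": mito})

    def test_mito_over_cap_excluded(self):
        keep, _ = q.apply_qc_filter(
            self._table([3000], [20_000], [0.06]), "mouse_hepatocyte")
        assert not keep[0]

    def test_boundary_values_kept(self):
        # thresholds are strict ("exceeding", "fewer than", "greater than")
        keep, _ = q.apply_qc_filter(
            self._table([1500, 6000], [40_000, 40_000], [0.05, 0.05]),
            "human_hepatocyte")
        assert keep.all()

    def test_presets_match_published_thresholds(self):
        p = q.PRESETS
        assert (p["mouse_hepatocyte"].min_genes, p["mouse_hepatocyte"].max_genes,
                p["mouse_hepatocyte"].max_umi) == (2000, 10_000, 100_000)
        assert (p["mouse_hsc"].max_genes, p["mouse_hsc"].max_umi) == (7000, 50_000)
        assert (p["human_hepatocyte"].min_genes,
                p["human_hepatocyte"].max_umi) == (1500, 40_000)

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown"):
            q.apply_qc_filter(self._table([1], [1], [0.0]), "rat_hepatocyte")

    def test_agrees_with_per_cell_reevaluation(self):
        rng = np.random.default_rng(0)
        n = 10_000
        table = self._table(rng.integers(0, 12_000, n),
                            rng.integers(0, 120_000, n), rng.random(n) * 0.2)
        preset = q.PRESETS["mouse_hsc"]
        keep, _ = q.apply_qc_filter(table, preset)
        for i in range(n):
            row = table.iloc[i]
            expect = (row.mito_fraction <= 0.05
                      and 2000 <= row.detected_genes <= 7000
                      and row.total_umi <= 50_000)
            assert keep[i] == expect


class TestNormalize:
    def test_closed_form(self):
        x = np.zeros((1, 3))
        x[0] = [1, 4999, 5000]         # total 10000 -> count 1 maps to log(2)
        out = q.normalize_log(sp.csr_matrix(x)).toarray()
        assert out[0, 0] == pytest.approx(np.log(2.0))

    def test_scale_invariance_and_zero_cells(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 30, size=(5, 8))
        x[2] = 0
        a = q.normalize_log(sp.csr_matrix(x)).toarray()
        b = q.normalize_log(sp.csr_matrix(x * 7)).toarray()
        np.testing.assert_allclose(a, b, atol=1e-12)
        assert (a[2] == 0).all()

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 50, size=(50, 20)).astype(float)
        got = q.normalize_log(sp.csr_matrix(x)).toarray()
        tot = x.sum(1, keepdims=True)
        expect = np.log1p(np.divide(x * 1e4, tot, out=np.zeros_like(x),
                                    where=tot > 0))
        np.testing.assert_allclose(got, expect, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=1, max_value=50))
    def test_monotone_within_cell(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 40, size=(1, 12))
        out = q.normalize_log(sp.csr_matrix(x.astype(float))).toarray()[0]
        order = np.argsort(x[0])
        assert (np.diff(out[order]) >= -1e-12).all()


class TestClustering:
    def _two_pops(self, n=120, sep=4.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(1.0, 1.0, size=(n, 40))
        x[n // 2:, :10] += sep
        return sp.csr_matrix(np.abs(x))

    def test_separated_populations_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        x = self._two_pops()
        labels = q.cluster_cells(x, n_hvg=40, n_pcs=5, n_clusters=2, seed=0)
        truth = np.repeat([0, 1], 60)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_identical_cells_single_cluster(self):
        x = sp.csr_matrix(np.ones((30, 10)))
        labels = q.cluster_cells(x, n_hvg=10, n_pcs=2, seed=0)
        assert len(np.unique(labels)) == 1

    def test_deterministic_given_seed(self):
        x = self._two_pops(seed=3)
        a = q.cluster_cells(x, n_hvg=40, n_pcs=5, seed=7)
        b = q.cluster_cells(x, n_hvg=40, n_pcs=5, seed=7)
        assert (a == b).all()

    def test_too_many_pcs_rejected(self):
        with pytest.raises(ValueError, match="n_pcs"):
            q.cluster_cells(self._two_pops(n=10), n_hvg=40, n_pcs=40)


class TestSignatureScore:
    def test_single_gene_equals_its_value(self):
        x = sp.csr_matrix(np.array([[1.0, 2.0], [0.5, 3.0]]))
        s = q.signature_score(x, ["a", "b"], ["b"])
        np.testing.assert_allclose(s, [2.0, 3.0])

    def test_duplicates_collapsed(self):
        x = sp.csr_matrix(np.array([[1.0, 3.0]]))
        s = q.signature_score(x, ["a", "b"], ["a", "a", "b"])
        assert s[0] == pytest.approx(2.0)

    def test_all_missing_raises(self):
        x = sp.csr_matrix(np.ones((2, 2)))
        with pytest.raises(ValueError, match="none"):
            q.signature_score(x, ["a", "b"], ["zzz"])


class TestContaminantExclusion:
    def _panel(self, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(1.0, 0.2, size=(90, 20)).clip(0)
        labels = np.repeat([0, 1, 2], 30)
        genes = [f"g{i}" for i in range(18)] + ["Ptprc", "Dcn"]
        x[labels == 2, 18:] += 5.0          # planted immune/stromal cluster
        return sp.csr_matrix(x), genes, labels

    def test_planted_marker_cluster_dropped(self):
        x, genes, labels = self._panel()
        mask = q.exclude_contaminant_clusters(x, genes, labels,
                                              ["Ptprc", "Dcn", "Pecam1"])
        assert (~mask[labels == 2]).all()
        assert mask[labels != 2].all()

    def test_absent_markers_keep_everything(self):
        x, genes, labels = self._panel()
        warns = []
        mask = q.exclude_contaminant_clusters(x, genes[:-2] + ["h1", "h2"],
                                              labels, ["Ptprc"],
                                              warn=warns.append)
        assert mask.all() and warns

    def test_vacuous_rule_keeps_everything(self):
        x, genes, labels = self._panel()
        mask = q.exclude_contaminant_clusters(x, genes, labels, ["Ptprc"],
                                              marker_fold=np.inf)
        assert mask.all()

    def test_masks_compose_with_qc_filter(self, qc_bundle):
        # contaminant exclusion on the QC-filtered subset equals composing
        # the two masks
        ad = qc_bundle.counts_mouse
        table = q.compute_cell_qc(ad)
        keep, _ = q.apply_qc_filter(table, "mouse_hepatocyte")
        logn = q.normalize_log(ad.X)
        labels = np.arange(ad.n_obs) % 3   # arbitrary grouping
        sub = q.exclude_contaminant_clusters(
            q.normalize_log(ad.X[keep]), ad.var_names, labels[keep], ["Ptprc"])
        both = q.exclude_contaminant_clusters(
            logn, ad.var_names, labels, ["Ptprc"])
        np.testing.assert_array_equal(sub, both[keep])


class TestZones:
    def _panel(self):
        genes = ["Sds", "Cyp2f2", "Hamp", "Igfbp2", "Glul", "Cyp2e1", "x"]
        return genes

    def test_pericentral_markers_give_zone3(self):
        genes = self._panel()
        x = np.zeros((1, 7))
        x[0, 4:6] = 2.0                    # only Glul and Cyp2e1
        out = q.assign_zones(sp.csr_matrix(x), genes)
        assert out.loc[0, "zone"] == "zone3"

    def test_exact_tie_is_unassigned(self):
        genes = self._panel()
        out = q.assign_zones(sp.csr_matrix(np.zeros((1, 7))), genes)
        assert out.loc[0, "zone"] == "unassigned"

    def test_missing_zone_named_in_error(self):
        with pytest.raises(ValueError, match="zone2"):
            q.assign_zones(sp.csr_matrix(np.ones((2, 2))), ["Sds", "Glul"])

    def test_gene_permutation_invariance(self, desk_bundle):
        ad = desk_bundle.counts_mouse
        logn = q.normalize_log(ad.X)
        base = q.assign_zones(logn, ad.var_names)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ad.n_vars)
        permuted = q.assign_zones(logn[:, perm],
                                  np.asarray(ad.var_names)[perm])
        assert (base["zone"].to_numpy() == permuted["zone"].to_numpy()).all()

    def test_planted_zones_recovered(self, qc_bundle):
        ad = qc_bundle.counts_mouse
        truth = qc_bundle.truth["cells_mouse"]
        intact = ~truth["outlier"].to_numpy()
        out = q.assign_zones(q.normalize_log(ad.X[intact]), ad.var_names)
        agree = (out["zone"].to_numpy()
                 == truth.loc[intact, "zone"].to_numpy()).mean()
        assert agree >= 0.9
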