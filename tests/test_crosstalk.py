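"""Receptor-ligand permutation test: gates, p-value floor, type-I error."""

import importlib.resources as ir

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from glicomix import crosstalk as ct
from glicomix import qc


def _null_adata(n_cells=240, n_genes=40, seed=0, rate=2.0):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate, size=(n_cells, n_genes)).astype(np.int32) + 1
    var = pd.DataFrame({"symbol": [f"L{j}" for j in range(n_genes)],
                        "chrom": ["chr1"] * n_genes,
                        "pos": np.arange(1, n_genes + 1)})
    var = var.set_index("symbol", drop=False).rename_axis(None)
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    a = ad.AnnData(X=counts, obs=obs, var=var)
    a.uns["layer"] = "raw"
    return qc.normalize(a)


def _pairs(n):
    return [ct.LRPair(f"p{j}", (f"L{2 * j}",), (f"L{2 * j + 1}",))
            for j in range(n)]


class TestReadPairs:
    def test_packaged_table_parses(self):
        path = ir.files("glicomix").joinpath("data/lr_pairs.tsv")
        pairs = ct.read_lr_pairs(str(path))
        assert len(pairs) >= 10
        ids = [p.pair_id for p in pairs]
        assert len(set(ids)) == len(ids)
        assert any(len(p.ligand_genes) > 1 or len(p.receptor_genes) > 1
                   for p in pairs)

    def test_duplicate_ids_raise(self, tmp_path):
        path = tmp_path / "lr.tsv"
        path.write_text("pair_id\tligand_genes\treceptor_genes\n"
                        "x\tA\tB\nx\tC\tD\n")
        with pytest.raises(ValueError, match="duplicate"):
            ct.read_lr_pairs(str(path))


class TestPrepare:
    def test_excluded_types_removed(self):
        a = _null_adata(60, 20)
        labels = np.array(["t1"] * 30 + ["t2"] * 20 + ["drop"] * 10)
        sub, lab = ct.prepare_crosstalk_input(a, labels,
                                              excluded_types=("drop",),
                                              n_hvg=a.n_vars)
        assert sub.n_obs == 50 and "drop" not in lab

    def test_lr_genes_kept_beyond_hvgs(self):
        a = _null_adata(100, 30)
        labels = np.array(["t1", "t2"] * 50)
        pairs = [ct.LRPair("p", ("L0",), ("L1",))]
        sub, _ = ct.prepare_crosstalk_input(a, labels, n_hvg=5, pairs=pairs)
        assert {"L0", "L1"} <= set(sub.var_names)
        assert sub.n_vars <= 7

    def test_all_cells_excluded_raises(self):
        a = _null_adata(10, 5)
        with pytest.raises(ValueError, match="all cells"):
            ct.prepare_crosstalk_input(a, np.array(["x"] * 10),
                                       excluded_types=("x",))


class TestPermutationTest:
    def test_pvalue_floor(self):
        a = _null_adata(120, 10, seed=1)
        labels = np.array(["t1", "t2"] * 60)
        res = ct.lr_permutation_test(a, labels, _pairs(2),
                                     n_permutations=100, seed=0)
        assert (res.table["pval"] >= 1 / 101 - 1e-12).all()
        assert (res.table["pval"] <= 1.0).all()

    def test_planted_interaction_detected(self):
        a = _null_adata(200, 10, seed=2)
        labels = np.array(["src", "dst"] * 100)
        x = a.X.copy()
        x[labels == "src", 0] += 3.0   # ligand L0 high in src
        x[labels == "dst", 1] += 3.0   # receptor L1 high in dst
        a.X = x
        res = ct.lr_permutation_test(a, labels, _pairs(1),
                                     n_permutations=200, seed=0)
        t = res.table.set_index(["cluster_a", "cluster_b"])
        assert t.loc[("src", "dst"), "significant"]

    def test_gate_forces_p_one(self):
        a = _null_adata(100, 10, seed=3)
        x = a.X.copy()
        x[:, 0] = 0.0                  # ligand never expressed
        a.X = x
        labels = np.array(["t1", "t2"] * 50)
        res = ct.lr_permutation_test(a, labels, _pairs(1),
                                     n_permutations=100, seed=0)
        assert (res.table["pval"] == 1.0).all()
        assert not res.table["significant"].any()

    def test_relaxed_gate_enlarges_significant_set(self):
        a = _null_adata(200, 10, seed=4)
        labels = np.array(["src", "dst"] * 100)
        rng = np.random.default_rng(4)
        x = a.X.copy()
        # strong but sparse signal: ligand/receptor in ~half of the cells
        x[:, 0] = np.where((labels == "src") & (rng.random(200) < 0.5),
                           5.0, 0.0)
        x[:, 1] = np.where((labels == "dst") & (rng.random(200) < 0.5),
                           5.0, 0.0)
        a.X = x
        strict = ct.lr_permutation_test(a, labels, _pairs(1), 150,
                                        min_expressed_fraction=0.9, seed=0)
        loose = ct.lr_permutation_test(a, labels, _pairs(1), 150,
                                       min_expressed_fraction=0.0, seed=0)
        s_strict = set(map(tuple, strict.table.loc[
            strict.table["significant"],
            ["cluster_a", "cluster_b", "pair_id"]].to_numpy()))
        s_loose = set(map(tuple, loose.table.loc[
            loose.table["significant"],
            ["cluster_a", "cluster_b", "pair_id"]].to_numpy()))
        assert s_strict <= s_loose
        assert len(s_loose) > len(s_strict)

    def test_missing_genes_skipped_and_recorded(self):
        a = _null_adata(60, 6, seed=5)
        labels = np.array(["t1", "t2"] * 30)
        pairs = [ct.LRPair("ok", ("L0",), ("L1",)),
                 ct.LRPair("bad", ("L0",), ("ABSENT",))]
        res = ct.lr_permutation_test(a, labels, pairs, 100, seed=0)
        assert res.skipped_pairs == [("bad", ["ABSENT"])]
        assert set(res.table["pair_id"]) == {"ok"}

    def test_type_I_error_matches_alpha(self):
        """Under label-shuffled null data the rejection rate over 512
        ordered-cluster-pair tests must sit near alpha = 0.05."""
        n_tests, n_rej = 0, 0
        for seed in range(4):
            a = _null_adata(240, 16, seed=10 + seed)
            rng = np.random.default_rng(seed)
            labels = rng.choice(["a", "b", "c", "d"], size=240)
            res = ct.lr_permutation_test(a, labels, _pairs(8),
                                         n_permutations=199, alpha=0.05,
                                         seed=seed)
            n_tests += len(res.table)
            n_rej += int(res.table["significant"].sum())
        assert n_tests >= 500
        rate = n_rej / n_tests
        se = np.sqrt(0.05 * 0.95 / n_tests)
        assert abs(rate - 0.05) < 4 * se + 0.01

    def test_validation(self):
        a = _null_adata(20, 6)
        labels = np.array(["t1", "t2"] * 10)
        with pytest.raises(ValueError, match="100 permutations"):
            ct.lr_permutation_test(a, labels, _pairs(1), n_permutations=10)
        with pytest.raises(ValueError, match="2 clusters"):
            ct.lr_permutation_test(a, np.array(["t"] * 20), _pairs(1), 100)
        raw = a.copy()
        raw.uns["layer"] = "raw"
        with pytest.raises(ValueError, match="normalized"):
            ct.lr_permutation_test(raw, labels, _pairs(1), 100)


class TestSummaries:
    def _result(self):
        a = _null_adata(200, 12, seed=6)
        labels = np.array(["tumor", "astro", "neuron", "npc"] * 50)
        x = a.X.copy()
        x[labels == "astro", 0] += 3.0
        x[labels == "tumor", 1] += 3.0
        a.X = x
        return ct.lr_permutation_test(a, labels, _pairs(3), 150, seed=0)

    def test_counts_match_table(self):
        res = self._result()
        counts = ct.interaction_counts(res)
        assert counts.to_numpy().sum() == res.table["significant"].sum()
        sym = ct.interaction_counts(res, symmetrize=True)
        assert (sym.to_numpy() == counts.to_numpy()
                + counts.to_numpy().T).all()

    def test_directional_filter(self):
        res = self._result()
        edges = ct.directional_filter(res, "tumor")
        assert (edges["cluster_b"] == "tumor").all()
        assert (edges["cluster_a"] != "tumor").all()
        assert edges["significant"].all()
        want = res.table[(res.table["significant"])
                         & (res.table["cluster_b"] == "tumor")
                         & (res.table["cluster_a"] != "tumor")]
        assert len(edges) == len(want)

    def test_unknown_tumor_cluster_raises(self):
        res = self._result()
        with pytest.raises(ValueError, match="unknown tumor cluster"):
            ct.directional_filter(res, "NOPE")
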