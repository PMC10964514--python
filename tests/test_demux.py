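"""Mixture-model demultiplexing, CNV labeling, rescue and fractions."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glicomix import cnv, demux, qc, sim


def _acm(ref, alt):
    ref = np.asarray(ref, np.int32)
    alt = np.asarray(alt, np.int32)
    s = ref.shape[1]
    sites = pd.DataFrame({"chrom": ["chr1"] * s,
                          "pos": np.arange(1, s + 1) * 100,
                          "ref": ["A"] * s, "alt": ["C"] * s})
    return sim.AlleleCounts(sites, ref, alt,
                            [f"c{i}" for i in range(ref.shape[0])])


def _oracle_loglik(acm, error_rate=1e-3):
    """Best observed-data mixture loglik over ALL theta state combinations
    (pi fixed at 0.5); a lower bound on the global optimum over free pi."""
    eps = max(error_rate, 1e-6)
    states = (eps, 0.5, 1.0 - eps)
    s = acm.alt_counts.shape[1]
    best = -np.inf
    for th_a in itertools.product(states, repeat=s):
        for th_b in itertools.product(states, repeat=s):
            theta = np.array([th_a, th_b])
            best = max(best, demux.mixture_loglik(acm, theta))
    return best


class TestMixtureFit:
    def test_clean_split_recovered(self):
        # 6 cells: first 3 pure-ref at site0/alt at site1, last 3 reversed
        ref = np.array([[9, 0]] * 3 + [[0, 9]] * 3)
        alt = np.array([[0, 9]] * 3 + [[9, 0]] * 3)
        out, theta = demux.fit_two_genotype_mixture(_acm(ref, alt))
        lab = out["label"].to_numpy()
        assert len(set(lab[:3])) == 1 and len(set(lab[3:])) == 1
        assert lab[0] != lab[3]
        assert set(lab) <= {"A", "B"}

    def test_posteriors_sum_to_one(self, small_sim):
        _, _, _, acm, _ = small_sim
        out, _ = demux.fit_two_genotype_mixture(acm, seed=0)
        assert np.allclose(out["posterior_a"] + out["posterior_b"], 1.0)
        assert set(out.columns) == set(demux.ASSIGN_COLUMNS)

    def test_zero_coverage_cell_unassigned(self):
        ref = np.array([[9, 0], [0, 9], [0, 0]])
        alt = np.array([[0, 9], [9, 0], [0, 0]])
        out, _ = demux.fit_two_genotype_mixture(_acm(ref, alt))
        assert out["label"].iloc[2] == "unassigned"

    def test_accuracy_on_simulation(self, small_sim):
        _, _, _, acm, truth = small_sim
        out, _ = demux.fit_two_genotype_mixture(acm, seed=1)
        assigned = out["label"].isin(["A", "B"]).to_numpy()
        # component letters are arbitrary: take best of both polarities
        pred = out["label"].to_numpy()[assigned]
        true = truth.genotype_labels[assigned]
        acc = max((pred == true).mean(),
                  (np.where(pred == "A", "B", "A") == true).mean())
        assert acc >= 0.99
        assert assigned.mean() > 0.5

    def test_loglik_beats_enumeration_oracle_on_tiny_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(8):
            n_cells = int(rng.integers(2, 5))
            n_sites = int(rng.integers(1, 4))
            depth = rng.poisson(6.0, size=(n_cells, n_sites))
            alt = rng.binomial(depth, rng.choice([0.0, 0.5, 1.0],
                                                 size=n_sites))
            acm = _acm(depth - alt, alt)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # degenerate draws may warn
                out, _ = demux.fit_two_genotype_mixture(acm, seed=trial)
            assert out.attrs["loglik"] >= _oracle_loglik(acm) - 1e-6

    def test_uninformative_sites_warn_and_unassign(self):
        rng = np.random.default_rng(1)
        depth = rng.poisson(8.0, size=(12, 3))
        alt = rng.binomial(depth, 0.5)  # every cell het everywhere
        with pytest.warns(UserWarning, match="no informative sites"):
            out, _ = demux.fit_two_genotype_mixture(_acm(depth - alt, alt))
        assert (out["label"] == "unassigned").all()

    def test_deterministic_given_seed(self, small_sim):
        _, _, _, acm, _ = small_sim
        a, ta = demux.fit_two_genotype_mixture(acm, seed=5)
        b, tb = demux.fit_two_genotype_mixture(acm, seed=5)
        assert (a["label"] == b["label"]).all()
        assert (ta == tb).all()

    def test_input_validation(self):
        with pytest.raises(ValueError, match="2 cells"):
            demux.fit_two_genotype_mixture(_acm([[1]], [[0]]))
        with pytest.raises(ValueError, match="coverage"):
            demux.fit_two_genotype_mixture(_acm([[0], [0]], [[0], [0]]))


class TestCNVLabeling:
    def test_reference_cells_near_zero_tumor_elevated(self, small_sim):
        _, cfg, adata, _, truth = small_sim
        norm = qc.normalize(adata.copy())
        ref_mask = truth.genotype_labels == "A"
        prof = cnv.infer_cnv(norm, ref_mask)
        assert prof.aneuploidy[ref_mask].mean() < \
            prof.aneuploidy[~ref_mask].mean()
        # gained segment: tumor cells score positive on those windows
        seg = cfg.cnv_segments[0]
        gain_cols = slice(seg.start_gene + 10, seg.end_gene - 10)
        assert prof.scores[~ref_mask, gain_cols].mean() > \
            prof.scores[ref_mask, gain_cols].mean() + 0.01

    def test_label_components_by_cnv(self, small_sim):
        _, _, adata, acm, truth = small_sim
        norm = qc.normalize(adata.copy())
        out, _ = demux.fit_two_genotype_mixture(acm, seed=2)
        major = out.loc[out["label"] != "unassigned", "label"] \
            .value_counts().idxmax()
        prof = cnv.infer_cnv(norm, (out["label"] == major).to_numpy())
        lab = demux.label_components_by_cnv(out, prof)
        assigned = lab["label"].isin(["A", "B"]).to_numpy()
        pred_tumor = (lab["genotype"].to_numpy() == "tumor")[assigned]
        true_tumor = (truth.genotype_labels == "B")[assigned]
        assert (pred_tumor == true_tumor).mean() >= 0.99

    def test_tie_raises(self):
        an = np.array([1.0, 1.0, 2.0, 2.0])
        prof = cnv.CNVProfile(np.zeros((4, 2)), np.arange(2),
                              np.array(["chr1"] * 2), 1,
                              [f"c{i}" for i in range(4)], an)
        out = pd.DataFrame({"barcode": [f"c{i}" for i in range(4)],
                            "posterior_a": 1.0, "posterior_b": 0.0,
                            "label": ["A", "B", "A", "B"],
                            "method": "mixture", "genotype": pd.NA})
        with pytest.raises(ValueError, match="tie"):
            demux.label_components_by_cnv(out, prof)

    def test_empty_component_raises(self):
        prof = cnv.CNVProfile(np.zeros((2, 2)), np.arange(2),
                              np.array(["chr1"] * 2), 1, ["c0", "c1"],
                              np.array([0.0, 1.0]))
        out = pd.DataFrame({"barcode": ["c0", "c1"],
                            "posterior_a": 1.0, "posterior_b": 0.0,
                            "label": ["A", "A"], "method": "mixture",
                            "genotype": pd.NA})
        with pytest.raises(ValueError, match="no assigned"):
            demux.label_components_by_cnv(out, prof)

    def test_infer_cnv_validation(self, small_sim):
        _, _, adata, _, _ = small_sim
        with pytest.raises(ValueError, match="normalized"):
            cnv.infer_cnv(adata, np.ones(adata.n_obs, bool))
        norm = qc.normalize(adata.copy())
        with pytest.raises(ValueError, match="empty"):
            cnv.infer_cnv(norm, np.zeros(norm.n_obs, bool))


class TestRescue:
    def test_full_chain_rescues_everything(self, small_sim):
        _, _, adata, acm, truth = small_sim
        norm = qc.normalize(adata.copy())
        out, _ = demux.fit_two_genotype_mixture(acm, seed=3)
        major = out.loc[out["label"] != "unassigned", "label"] \
            .value_counts().idxmax()
        prof = cnv.infer_cnv(norm, (out["label"] == major).to_numpy())
        out = demux.label_components_by_cnv(out, prof)
        n_un = int((out["label"] == "unassigned").sum())
        res = demux.rescue_unassigned(out, norm, n_hvg=norm.n_vars)
        assert (res["label"] != "unassigned").all()
        assert (res["method"] == "neighbor-rescue").sum() == n_un
        # final accuracy of organoid/tumor calls vs simulation truth
        pred = np.where(res["genotype"] == "tumor", "B", "A")
        assert (pred == truth.genotype_labels).mean() >= 0.95

    def test_noop_when_all_assigned(self, small_sim):
        _, _, adata, _, _ = small_sim
        norm = qc.normalize(adata.copy())
        out = pd.DataFrame({"barcode": norm.obs_names,
                            "posterior_a": 1.0, "posterior_b": 0.0,
                            "label": "A", "method": "mixture",
                            "genotype": "organoid"})
        res = demux.rescue_unassigned(out, norm)
        assert (res["method"] == "mixture").all()

    def test_all_unassigned_raises(self, small_sim):
        _, _, adata, _, _ = small_sim
        norm = qc.normalize(adata.copy())
        out = pd.DataFrame({"barcode": norm.obs_names,
                            "posterior_a": 0.5, "posterior_b": 0.5,
                            "label": "unassigned", "method": "mixture",
                            "genotype": pd.NA})
        with pytest.raises(ValueError, match="no assigned"):
            demux.rescue_unassigned(out, norm)


class TestFractions:
    def _assign(self):
        return pd.DataFrame({
            "barcode": [f"c{i}" for i in range(6)],
            "posterior_a": 1.0, "posterior_b": 0.0,
            "label": ["A", "A", "B", "B", "unassigned", "A"],
            "method": "mixture",
            "genotype": ["organoid", "organoid", "tumor", "tumor",
                         pd.NA, "organoid"],
        })

    def test_accounting(self):
        samples = pd.Series(["s1"] * 3 + ["s2"] * 3,
                            index=[f"c{i}" for i in range(6)])
        tab = demux.genotype_fractions(self._assign(), samples)
        tab = tab.set_index("sample")
        assert (tab["n_labeled"] + tab["n_unassigned"]
                == tab["n_cells"]).all()
        assert tab.loc["s1", "tumor_fraction"] == pytest.approx(1 / 3)
        assert tab.loc["s2", "tumor_fraction"] == pytest.approx(1 / 2)

    def test_missing_sample_label_raises(self):
        samples = pd.Series(["s1"] * 5, index=[f"c{i}" for i in range(5)])
        with pytest.raises(ValueError, match="no sample label"):
            demux.genotype_fractions(self._assign(), samples)
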