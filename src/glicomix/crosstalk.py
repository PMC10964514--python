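"""Receptor-ligand crosstalk between cell-type clusters by permutation test.

For an ordered cluster pair (A, B) and a ligand-receptor pair, the observed
interaction score is the mean of the ligand's expression in A and the
receptor's expression in B (multi-gene complexes take the minimum member
mean). Significance comes from re-computing the score under random
shuffles of the cluster labels; a pair also has to pass an expressed-cell
fraction gate in both clusters. Interaction counts per cluster pair and a
directional filter to microenvironment-ligand -> tumor-receptor edges
reproduce the downstream summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from ._utils import as_dense


@dataclass
class LRPair:
    pair_id: str
    ligand_genes: tuple
    receptor_genes: tuple


def read_lr_pairs(path: str) -> list:
    """TSV with columns pair_id, ligand_genes, receptor_genes (';'-joined)."""
    df = pd.read_csv(path, sep="\t")
    if df["pair_id"].duplicated().any():
        raise ValueError("duplicate pair ids in LR table")
    return [LRPair(r.pair_id, tuple(str(r.ligand_genes).split(";")),
                   tuple(str(r.receptor_genes).split(";")))
            for r in df.itertuples(index=False)]


@dataclass
class InteractionResult:
    """Per (ligand cluster, receptor cluster, pair) permutation-test results."""

    table: pd.DataFrame   # cluster_a, cluster_b, pair_id, score, pval, significant
    alpha: float
    n_permutations: int
    min_expressed_fraction: float
    skipped_pairs: list = field(default_factory=list)


def prepare_crosstalk_input(adata: ad.AnnData, cell_type_labels,
                            excluded_types=(), n_hvg: int = 5000,
                            pairs: list | None = None):
    """Drop excluded cell types and restrict genes to HVGs plus LR genes."""
    labels = np.asarray(cell_type_labels)
    if len(labels) != adata.n_obs:
        raise ValueError("labels must cover all cells")
    keep = ~np.isin(labels, list(excluded_types))
    if not keep.any():
        raise ValueError("excluded types remove all cells")
    adata = adata[keep].copy()
    labels = labels[keep]
    genes = set(adata.var_names)
    if n_hvg < adata.n_vars:
        from .qc import select_hvg
        genes = set(select_hvg(adata, n_hvg))
    if pairs:
        lr_genes = {g for p in pairs
                    for g in (*p.ligand_genes, *p.receptor_genes)}
        genes |= lr_genes & set(adata.var_names)
    keep_genes = [g for g in adata.var_names if g in genes]
    return adata[:, keep_genes].copy(), labels


def _cluster_stats(x, onehot, counts):
    """Cluster means (clusters x genes) given a one-hot label matrix."""
    return (onehot.T @ x) / counts[:, None]


def lr_permutation_test(adata: ad.AnnData, labels, pairs: list,
                        n_permutations: int = 1000,
                        min_expressed_fraction: float = 0.10,
                        alpha: float = 0.05, seed: int = 0
                        ) -> InteractionResult:
    """Label-permutation test of receptor-ligand co-expression.

    p = (1 + #{null score >= observed}) / (n_permutations + 1), one-sided for
    enrichment; a zero observed score or a failed expressed-fraction gate
    forces p = 1. Pairs referencing absent genes are skipped and recorded.
    """
    if adata.uns.get("layer") != "normalized":
        raise ValueError("lr_permutation_test requires the normalized layer")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    labels = np.asarray(labels)
    clusters = list(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")

    present = set(adata.var_names)
    usable, skipped = [], []
    genes_needed = []
    for p in pairs:
        missing = [g for g in (*p.ligand_genes, *p.receptor_genes)
                   if g not in present]
        if missing:
            skipped.append((p.pair_id, missing))
        else:
            usable.append(p)
            genes_needed.extend((*p.ligand_genes, *p.receptor_genes))
    genes_needed = list(dict.fromkeys(genes_needed))
    gpos = {g: i for i, g in enumerate(genes_needed)}
    x = as_dense(adata[:, genes_needed].X)

    lab_idx = np.array([clusters.index(l) for l in labels])
    onehot = np.eye(len(clusters))[lab_idx]
    counts = onehot.sum(axis=0)
    means = _cluster_stats(x, onehot, counts)
    expr_frac = _cluster_stats((x > 0).astype(float), onehot, counts)

    def complex_stat(mat, genes):
        return mat[:, [gpos[g] for g in genes]].min(axis=1)

    lig_mean = np.stack([complex_stat(means, p.ligand_genes)
                         for p in usable], axis=1)      # clusters x pairs
    rec_mean = np.stack([complex_stat(means, p.receptor_genes)
                         for p in usable], axis=1)
    lig_ok = np.stack([complex_stat(expr_frac, p.ligand_genes)
                       for p in usable], axis=1) >= min_expressed_fraction
    rec_ok = np.stack([complex_stat(expr_frac, p.receptor_genes)
                       for p in usable], axis=1) >= min_expressed_fraction

    # observed scores for every ordered cluster pair: (A, B, pair)
    obs = 0.5 * (lig_mean[:, None, :] + rec_mean[None, :, :])
    gate = lig_ok[:, None, :] & rec_ok[None, :, :]

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_permutations):
        perm = rng.permutation(len(labels))
        pm = _cluster_stats(x[perm], onehot, counts)
        plig = np.stack([complex_stat(pm, p.ligand_genes)
                         for p in usable], axis=1)
        prec = np.stack([complex_stat(pm, p.receptor_genes)
                         for p in usable], axis=1)
        null = 0.5 * (plig[:, None, :] + prec[None, :, :])
        exceed += null >= obs - 1e-12
    pval = (1.0 + exceed) / (n_permutations + 1.0)
    pval = np.where(gate & (obs > 0), pval, 1.0)
    significant = (pval <= alpha) & gate & (obs > 0)

    rows = []
    for ia, ca in enumerate(clusters):
        for ib, cb in enumerate(clusters):
            for ip, p in enumerate(usable):
                rows.append((ca, cb, p.pair_id, obs[ia, ib, ip],
                             pval[ia, ib, ip], bool(significant[ia, ib, ip])))
    table = pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "pair_id",
                                        "score", "pval", "significant"])
    return InteractionResult(table, alpha, n_permutations,
                             min_expressed_fraction, skipped)


def interaction_counts(res: InteractionResult,
                       symmetrize: bool = False) -> pd.DataFrame:
    """Number of significant interactions per ordered cluster pair."""
    t = res.table
    clusters = list(pd.unique(pd.concat([t["cluster_a"], t["cluster_b"]])))
    out = pd.DataFrame(0, index=clusters, columns=clusters)
    sig = t[t["significant"]]
    for (ca, cb), grp in sig.groupby(["cluster_a", "cluster_b"]):
        out.loc[ca, cb] = len(grp)
    if symmetrize:
        out = out + out.T
    out.attrs["symmetrized"] = symmetrize
    return out


def directional_filter(res: InteractionResult, tumor_cluster) -> pd.DataFrame:
    """Significant microenvironment-ligand -> tumor-receptor interactions."""
    t = res.table
    known = set(t["cluster_a"]) | set(t["cluster_b"])
    if tumor_cluster not in known:
        raise ValueError(f"unknown tumor cluster {tumor_cluster!r}")
    keep = (t["significant"]
            & (t["cluster_a"] != tumor_cluster)
            & (t["cluster_b"] == tumor_cluster))
    return t[keep].reset_index(drop=True)
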