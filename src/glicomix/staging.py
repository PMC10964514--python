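"""Pseudo-bulk developmental staging and cross-dataset cluster comparison.

Single-cell samples are aggregated to pseudo-bulk profiles and staged by
Pearson correlation against an age-graded bulk reference series, using the
reference's most variable genes; correlations are averaged within reference
age groups and the best-matching age is the argmax. Cluster identities are
compared across datasets through marker-gene specificity scores (cluster
mean normalized expression over global mean) correlated over the shared
marker genes.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd

from ._utils import as_dense, cpm_log1p, vst_standardized_variance
from .sim import ReferenceSeries


def pseudobulk(adata: ad.AnnData, sample_labels) -> pd.DataFrame:
    """Per-sample sums of raw counts (genes x samples)."""
    counts = adata.layers["counts"] if "counts" in adata.layers else adata.X
    counts = as_dense(counts)
    sample_labels = pd.Series(np.asarray(sample_labels),
                              index=adata.obs_names)
    if sample_labels.isna().any():
        raise ValueError("every cell must carry a sample label")
    cols = {}
    for s, idx in sample_labels.groupby(sample_labels).groups.items():
        pos = [adata.obs_names.get_loc(i) for i in idx]
        cols[s] = counts[pos].sum(axis=0)
    return pd.DataFrame(cols, index=adata.var_names)


def stage_by_correlation(query: pd.DataFrame, ref: ReferenceSeries,
                         n_hvg: int = 2000) -> pd.DataFrame:
    """Mean Pearson r of each query profile against reference age groups.

    Variable genes are selected on the reference only (VST standardized
    variance); both sides are CPM + log1p normalized; Pearson correlations
    query-vs-each-reference-sample are averaged per reference age. Returns a
    query x age table with a ``best_age`` column (argmax age group).
    """
    shared = query.index.intersection(ref.expr.index)
    if len(shared) < max(2, min(n_hvg, 2)):
        raise ValueError("too few shared genes between query and reference")
    ref_counts = ref.expr.loc[shared]
    sv = vst_standardized_variance(ref_counts.to_numpy().T)
    n_hvg = min(n_hvg, len(shared))
    hvg = shared[np.argsort(-sv, kind="stable")[:n_hvg]]
    if len(hvg) < 2:
        raise ValueError("fewer than 2 shared variable genes")

    q = cpm_log1p(query.T.to_numpy())[:, [query.index.get_loc(g)
                                          for g in hvg]]
    r = cpm_log1p(ref.expr.T.to_numpy())[:, [ref.expr.index.get_loc(g)
                                             for g in hvg]]
    qz = q - q.mean(axis=1, keepdims=True)
    rz = r - r.mean(axis=1, keepdims=True)
    qn = np.sqrt((qz ** 2).sum(axis=1))
    rn = np.sqrt((rz ** 2).sum(axis=1))
    corr = (qz @ rz.T) / np.outer(qn, rn)

    corr_df = pd.DataFrame(corr, index=query.columns,
                           columns=ref.expr.columns)
    ages = ref.ages.loc[corr_df.columns]
    by_age = corr_df.T.groupby(ages.to_numpy()).mean().T
    by_age["best_age"] = by_age.idxmax(axis=1)
    return by_age


def specificity_scores(adata: ad.AnnData, cluster_labels,
                       marker_genes) -> pd.DataFrame:
    """Cluster specificity: cluster mean normalized counts / global mean.

    Normalization is counts-per-10,000 per cell. A uniformly expressed gene
    scores exactly 1 in every cluster; genes with zero global mean are
    dropped with a warning. Returns genes x clusters.
    """
    marker_genes = [g for g in marker_genes if g in adata.var_names]
    if not marker_genes:
        raise ValueError("no marker genes present in the matrix")
    counts = adata.layers["counts"] if "counts" in adata.layers else adata.X
    norm = cpm_log1p(as_dense(counts), target_sum=1e4)
    norm = np.expm1(norm)  # linear CP10K scale for the mean ratio
    cluster_labels = np.asarray(cluster_labels)
    pos = [adata.var_names.get_loc(g) for g in marker_genes]
    sub = norm[:, pos]
    global_mean = sub.mean(axis=0)
    keep = global_mean > 0
    if not keep.all():
        dropped = [g for g, k in zip(marker_genes, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} genes with zero global mean")
    out = {}
    for c in pd.unique(cluster_labels):
        out[c] = sub[cluster_labels == c].mean(axis=0)[keep] / \
            global_mean[keep]
    genes = [g for g, k in zip(marker_genes, keep) if k]
    return pd.DataFrame(out, index=genes)


def cross_dataset_correlation(a: pd.DataFrame, b: pd.DataFrame
                              ) -> pd.DataFrame:
    """Pearson r between cluster specificity profiles of two datasets.

    Restricted to the intersection of the two marker gene lists; clusters
    with constant scores over the intersection yield missing values.
    """
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("marker gene intersection has fewer than 3 genes")
    av = a.loc[shared]
    bv = b.loc[shared]
    out = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for ca in a.columns:
        for cb in b.columns:
            x, y = av[ca].to_numpy(), bv[cb].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                out.loc[ca, cb] = np.nan
            else:
                out.loc[ca, cb] = np.corrcoef(x, y)[0, 1]
    return out
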