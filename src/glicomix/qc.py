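"""Quality control, normalization, variable-gene selection and markers.

The filters mirror a standard droplet scRNA-seq workflow: cells are removed
when they detect fewer than 750 genes or exceed 10% mitochondrial counts;
ribosomal genes and genes detected in fewer than five cells are excluded;
expression is library-size corrected to 10,000 counts per cell and log1p
transformed; variable genes are ranked by standardized variance after a
variance-stabilizing mean-variance trend fit; cluster markers come from
one-vs-rest Wilcoxon rank-sum tests with Benjamini-Hochberg adjustment
within each cluster.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import as_dense, vst_standardized_variance


def _raw(adata: ad.AnnData) -> np.ndarray:
    if adata.uns.get("layer") == "normalized":
        raise ValueError("operation requires the raw count layer")
    return as_dense(adata.X)


def annotate_gene_flags(adata: ad.AnnData) -> ad.AnnData:
    """Fill missing mito/ribo flags from gene-symbol prefixes (MT-, RPL/RPS)."""
    sym = adata.var["symbol"].astype(str) if "symbol" in adata.var else \
        pd.Series(adata.var_names, index=adata.var_names)
    if "mito" not in adata.var:
        adata.var["mito"] = sym.str.upper().str.startswith("MT-").to_numpy()
    if "ribo" not in adata.var:
        adata.var["ribo"] = sym.str.upper().str.match(r"RP[LS]").to_numpy()
    return adata


def filter_cells(adata: ad.AnnData, min_genes: int = 750,
                 max_mito_fraction: float = 0.10) -> ad.AnnData:
    """Keep cells detecting >= ``min_genes`` genes with mito fraction <= cap."""
    annotate_gene_flags(adata)
    x = _raw(adata)
    detected = (x > 0).sum(axis=1)
    totals = x.sum(axis=1)
    mito = x[:, adata.var["mito"].to_numpy(bool)].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / totals, 0.0)
    keep = (detected >= min_genes) & (frac <= max_mito_fraction)
    if not keep.any():
        raise ValueError("all cells filtered out by QC thresholds")
    return adata[keep].copy()


def filter_genes(adata: ad.AnnData, min_cells: int = 5,
                 drop_ribosomal: bool = True) -> ad.AnnData:
    """Drop ribosomal genes and genes detected in fewer than ``min_cells`` cells."""
    annotate_gene_flags(adata)
    x = _raw(adata)
    detected_in = (x > 0).sum(axis=0)
    keep = detected_in >= min_cells
    if drop_ribosomal:
        keep &= ~adata.var["ribo"].to_numpy(bool)
    if not keep.any():
        raise ValueError("all genes filtered out")
    return adata[:, keep].copy()


def normalize(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """log1p(count / cell_total * target_sum); raw counts kept in a layer."""
    x = _raw(adata)
    totals = x.sum(axis=1)
    if (totals == 0).any():
        bad = adata.obs_names[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts")
    adata = adata.copy()
    adata.layers["counts"] = adata.X.copy()
    adata.X = np.log1p(x / totals[:, None] * target_sum)
    adata.uns["layer"] = "normalized"
    adata.uns["target_sum"] = target_sum
    return adata


def select_hvg(adata: ad.AnnData, n_top: int = 2000) -> list:
    """Top ``n_top`` genes by VST standardized variance on raw counts."""
    if adata.n_vars < n_top:
        raise ValueError(f"n_top={n_top} exceeds the {adata.n_vars} genes")
    counts = as_dense(adata.layers["counts"]) \
        if "counts" in adata.layers else _raw(adata)
    sv = vst_standardized_variance(counts)
    order = np.argsort(-sv, kind="stable")
    return list(adata.var_names[order[:n_top]])


# ---------------------------------------------------------------------------
# markers


def _ranksum_asymptotic(x: np.ndarray, in_grp: np.ndarray) -> tuple:
    """Vectorized tie-corrected normal-approximation rank-sum test.

    ``x``: cells x genes normalized values; returns (U, p) arrays per gene.
    """
    n1 = int(in_grp.sum())
    n2 = len(in_grp) - n1
    ranks = stats.rankdata(x, axis=0)
    r1 = ranks[in_grp].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    # tie correction per gene
    tie_term = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        _, cnt = np.unique(x[:, j], return_counts=True)
        tie_term[j] = (cnt ** 3 - cnt).sum()
    n = n1 + n2
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - mu - np.sign(u1 - mu) * 0.5) / sigma
    p = np.where(sigma > 0, 2 * stats.norm.sf(np.abs(z)), 1.0)
    return u1, np.clip(p, 0, 1)


def rank_markers(adata: ad.AnnData, labels) -> pd.DataFrame:
    """One-vs-rest two-sided Wilcoxon rank-sum markers per cluster.

    Exact enumeration (via :func:`glicomix.scoring.exact_rank_test`) is used
    when a comparison involves at most 50 cells in total, the tie-corrected
    normal approximation above. p-values are Benjamini-Hochberg adjusted
    within each cluster.
    """
    if adata.uns.get("layer") != "normalized":
        raise ValueError("rank_markers requires the normalized layer")
    labels = np.asarray(labels)
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    for c in clusters:
        if (labels == c).sum() < 2:
            raise ValueError(f"cluster {c!r} has fewer than 2 cells")
    x = as_dense(adata.X)
    rows = []
    small = x.shape[0] <= 50
    for c in clusters:
        in_grp = labels == c
        m_in = x[in_grp].mean(axis=0)
        m_out = x[~in_grp].mean(axis=0)
        lfc = np.log2((np.expm1(m_in) + 1e-9) / (np.expm1(m_out) + 1e-9))
        if small:
            from .scoring import exact_rank_test
            stats_u, pvals = [], []
            for j in range(x.shape[1]):
                p = exact_rank_test(x[in_grp, j], x[~in_grp, j])
                n1 = in_grp.sum()
                r1 = stats.rankdata(x[:, j])[in_grp].sum()
                stats_u.append(r1 - n1 * (n1 + 1) / 2)
                pvals.append(p)
            stats_u, pvals = np.array(stats_u), np.array(pvals)
        else:
            stats_u, pvals = _ranksum_asymptotic(x, in_grp)
        padj = multipletests(pvals, method="fdr_bh")[1]
        for j, g in enumerate(adata.var_names):
            rows.append((g, c, lfc[j], stats_u[j], pvals[j], padj[j]))
    return pd.DataFrame(rows, columns=["gene", "cluster", "log2fc",
                                       "statistic", "pval", "padj"])


def kmeans_clusters(adata: ad.AnnData, k: int, n_pcs: int = 30,
                    seed: int = 0) -> np.ndarray:
    """Convenience k-means clustering in PCA space (not a published method)."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    x = as_dense(adata.X)
    x = x - x.mean(axis=0)
    n_pcs = min(n_pcs, min(x.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return KMeans(n_clusters=k, n_init=5, random_state=seed).fit_predict(pcs)
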