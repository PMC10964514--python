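"""Inferred copy-number profiles from smoothed, reference-centered expression.

Genes are ordered genomically; each gene's normalized expression is centered
by the mean over an assumed-diploid reference cell set; a moving average over
consecutive genes within each chromosome smooths single-gene noise into
segment-level signal. A per-cell aneuploidy score (mean squared window
score) summarizes departure from the reference ploidy and is used to decide
which genotype component is the tumor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from ._utils import as_dense, genomic_order


@dataclass
class CNVProfile:
    """Windowed relative-expression scores per cell, in genomic gene order."""

    scores: np.ndarray          # cells x genes (window-averaged)
    gene_order: np.ndarray      # indices into the source var table
    chrom: np.ndarray           # chromosome per ordered gene
    window_genes: int
    cell_names: list
    aneuploidy: np.ndarray      # per-cell mean squared window score


def _moving_average(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with truncated edges."""
    kernel = np.ones(window)
    ones = np.convolve(np.ones(block.shape[1]), kernel, mode="same")
    out = np.empty_like(block)
    for i in range(block.shape[0]):
        out[i] = np.convolve(block[i], kernel, mode="same") / ones
    return out


def infer_cnv(adata: ad.AnnData, reference_mask, window_genes: int = 101
              ) -> CNVProfile:
    """Moving-average copy-number inference from normalized expression.

    ``reference_mask``: boolean per cell marking the assumed-diploid
    reference set used for centering.
    """
    if adata.uns.get("layer") != "normalized":
        raise ValueError("infer_cnv requires the normalized layer")
    if not {"chrom", "pos"} <= set(adata.var.columns):
        raise ValueError("gene genomic coordinates (chrom, pos) required")
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference cell set is empty")
    order = genomic_order(adata.var)
    x = as_dense(adata.X)[:, order]
    chrom = adata.var["chrom"].to_numpy()[order]
    centered = x - x[reference_mask].mean(axis=0)

    scores = np.empty_like(centered)
    truncated = []
    for c in pd.unique(chrom):
        cols = np.where(chrom == c)[0]
        w = window_genes
        if len(cols) < window_genes:
            truncated.append(str(c))
            w = len(cols)
        scores[:, cols] = _moving_average(centered[:, cols], w)
    if truncated:
        warnings.warn(f"window truncated on {len(truncated)} chromosome(s) "
                      f"with fewer than {window_genes} genes: "
                      f"{', '.join(truncated[:5])}...")
    aneuploidy = (scores ** 2).mean(axis=1)
    return CNVProfile(scores, order, chrom, window_genes,
                      list(adata.obs_names), aneuploidy)
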