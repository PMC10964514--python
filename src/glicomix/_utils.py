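"""Shared numerical helpers used across modules."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd


def as_dense(x) -> np.ndarray:
    """Return ``x`` as a dense 2-D float array (accepts scipy sparse)."""
    if hasattr(x, "toarray"):
        x = x.toarray()
    return np.asarray(x, dtype=float)


def cpm_log1p(counts: np.ndarray, target_sum: float = 1e6) -> np.ndarray:
    """Library-size normalize rows of ``counts`` to ``target_sum`` and log1p.

    Rows are units (cells or samples), columns genes. Zero-total rows are
    left as zeros rather than producing NaNs.
    """
    counts = as_dense(counts)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(totals > 0, counts / totals * target_sum, 0.0)
    return np.log1p(scaled)


def vst_standardized_variance(counts: np.ndarray, clip: float | None = None,
                              degree: int = 2) -> np.ndarray:
    """Per-gene standardized variance after a variance-stabilizing trend fit.

    Fits a polynomial of ``log10(variance)`` on ``log10(mean)`` over genes
    with positive variance, standardizes each raw count by the trend's
    expected standard deviation, clips at ``sqrt(n_cells)`` (unless
    overridden) and returns the variance of the clipped standardized values
    per gene. Genes with zero variance get standardized variance 0.

    ``counts``: units x genes raw count matrix.
    """
    x = as_dense(counts)
    n, _ = x.shape
    mu = x.mean(axis=0)
    var = x.var(axis=0)
    out = np.zeros_like(mu)
    ok = (mu > 0) & (var > 0)
    if ok.sum() < degree + 1:
        # too few informative genes to fit a trend: fall back to raw variance
        out[ok] = var[ok]
        return out
    lm, lv = np.log10(mu[ok]), np.log10(var[ok])
    coef = np.polyfit(lm, lv, deg=degree)
    exp_sd = np.sqrt(10.0 ** np.polyval(coef, lm))
    if clip is None:
        clip = np.sqrt(n)
    z = (x[:, ok] - mu[ok]) / exp_sd
    z = np.minimum(z, clip)
    out[ok] = z.var(axis=0)
    return out


_CHROM_RE = re.compile(r"^(chr)?(.+)$", re.IGNORECASE)


def chrom_sort_key(chrom: str):
    """Sort key giving natural genomic ordering: 1..22, X, Y, MT, others."""
    body = _CHROM_RE.match(str(chrom)).group(2)
    try:
        return (0, int(body), "")
    except ValueError:
        order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
        return (0, order.get(body.upper(), 99), body)


def genomic_order(var: pd.DataFrame) -> np.ndarray:
    """Indices sorting a gene table with ``chrom``/``pos`` columns genomically."""
    chroms = sorted(set(var["chrom"]), key=chrom_sort_key)
    rank = {c: i for i, c in enumerate(chroms)}
    cr = np.array([rank[c] for c in var["chrom"]])
    return np.lexsort((np.asarray(var["pos"]), cr))
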