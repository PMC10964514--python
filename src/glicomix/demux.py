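"""Reference-free two-genotype demultiplexing from per-cell SNP allele counts.

A two-component binomial mixture model is fit by EM: each component carries
a diploid genotype state per site, so its alt-read probability is restricted
to {error_rate, 0.5, 1 - error_rate}. Cells are assigned to the component
with posterior above a threshold ("unambiguous" assignment); remaining cells
are rescued by majority vote among nearest assigned neighbors in expression
PCA space. Components are anonymous until labeled organoid/tumor by their
inferred-CNV aneuploidy.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._utils import as_dense
from .cnv import CNVProfile
from .sim import AlleleCounts

ASSIGN_COLUMNS = ["barcode", "posterior_a", "posterior_b", "label", "method",
                  "genotype"]


def _component_loglik(alt, tot, theta):
    """Per-cell log-likelihood under alt probabilities ``theta`` (per site)."""
    return alt @ np.log(theta) + (tot - alt) @ np.log1p(-theta)


def _m_step_theta(alt, tot, resp, states):
    """Pick the ML genotype state per (component, site).

    ``resp``: cells x 2 responsibilities. Returns theta (2 x sites).
    """
    a_w = resp.T @ alt          # 2 x sites expected alt counts
    n_w = resp.T @ tot
    best = np.full((2, alt.shape[1]), states[0])
    best_score = np.full((2, alt.shape[1]), -np.inf)
    for v in states:
        score = a_w * np.log(v) + (n_w - a_w) * np.log1p(-v)
        upd = score > best_score
        best[upd] = v
        best_score[upd] = score[upd]
    return best


def fit_two_genotype_mixture(ac: AlleleCounts, error_rate: float = 1e-3,
                             max_iter: int = 200, tol: float = 1e-8,
                             posterior_threshold: float = 0.99,
                             seed: int = 0, n_restarts: int = 5
                             ) -> tuple[pd.DataFrame, np.ndarray]:
    """EM fit of the two-genotype binomial mixture.

    Returns (assignments, theta) where assignments has one row per cell
    (barcode, posterior_a, posterior_b, label in {A, B, unassigned}, method,
    genotype) and theta is the 2 x sites matrix of inferred per-site alt
    probabilities. Component order is arbitrary; downstream labeling by CNV
    resolves organoid vs tumor.
    """
    alt = np.asarray(ac.alt_counts, dtype=float)
    tot = np.asarray(ac.totals, dtype=float)
    n_cells, n_sites = alt.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if not (tot.sum(axis=0) > 0).any():
        raise ValueError("no site has nonzero coverage")
    eps = max(error_rate, 1e-6)
    states = (eps, 0.5, 1.0 - eps)
    rng = np.random.default_rng(seed)

    # k-means++ initialization on zero-imputed alt-fraction vectors
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)

    from sklearn.cluster import KMeans

    inits = []
    for r in range(n_restarts):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(n_clusters=2, init="k-means++", n_init=1,
                        random_state=int(rng.integers(2**31 - 1)))
            hard = km.fit_predict(frac)
        inits.append(np.where(hard[:, None] == np.arange(2)[None, :],
                              0.95, 0.05))
    if n_cells <= 10:
        # tiny instances: seed EM from every hard bipartition so the global
        # optimum cannot be missed
        for code in range(1, 2 ** (n_cells - 1)):
            hard = (code >> np.arange(n_cells)) & 1
            inits.append(np.eye(2)[hard])

    best = None
    for resp in inits:
        pi = np.full(2, 0.5)
        prev_ll = -np.inf
        for _ in range(max_iter):
            theta = _m_step_theta(alt, tot, resp, states)
            ll_cg = np.stack([_component_loglik(alt, tot, theta[g])
                              for g in range(2)], axis=1)
            ll_cg = ll_cg + np.log(pi)[None, :]
            norm = logsumexp(ll_cg, axis=1)
            resp = np.exp(ll_cg - norm[:, None])
            pi = np.clip(resp.mean(axis=0), 1e-12, None)
            pi = pi / pi.sum()
            ll = norm.sum()
            if ll - prev_ll < tol * abs(ll) and ll >= prev_ll:
                prev_ll = ll
                break
            prev_ll = ll
        if best is None or prev_ll > best[0]:
            best = (prev_ll, theta, resp, pi)

    # Local-search polish: soft responsibilities let the majority component
    # leak weight into the minority's per-site counts, which can trap EM in
    # a local optimum with mislabeled genotype states. Re-fitting theta from
    # hard MAP assignments and iterating escapes that basin; the result is
    # kept only when the observed-data likelihood improves.
    ll, theta, resp, pi = best
    for _ in range(20):
        hard = np.eye(2)[resp.argmax(axis=1)]
        theta_h = _m_step_theta(alt, tot, hard, states)
        ll_cg = np.stack([_component_loglik(alt, tot, theta_h[g])
                          for g in range(2)], axis=1) + np.log(pi)[None, :]
        norm = logsumexp(ll_cg, axis=1)
        ll_h = norm.sum()
        if ll_h <= ll + 1e-9:
            break
        ll, theta = ll_h, theta_h
        resp = np.exp(ll_cg - norm[:, None])
        pi = np.clip(resp.mean(axis=0), 1e-12, None)
        pi = pi / pi.sum()
        best = (ll, theta, resp, pi)

    _, theta, resp, pi = best
    if np.allclose(theta[0], theta[1]):
        warnings.warn("no informative sites: components identical; "
                      "all cells unassigned")
        resp = np.full_like(resp, 0.5)

    post_a, post_b = resp[:, 0], resp[:, 1]
    label = np.where(np.maximum(post_a, post_b) >= posterior_threshold,
                     np.where(post_a >= post_b, "A", "B"), "unassigned")
    label[tot.sum(axis=1) == 0] = "unassigned"  # no evidence at all
    out = pd.DataFrame({
        "barcode": ac.barcodes,
        "posterior_a": post_a, "posterior_b": post_b,
        "label": label, "method": "mixture", "genotype": pd.NA,
    })
    out.attrs["loglik"] = best[0]
    out.attrs["pi"] = pi
    return out, theta


def mixture_loglik(ac: AlleleCounts, theta: np.ndarray,
                   pi=(0.5, 0.5)) -> float:
    """Observed-data log-likelihood of allele counts under (theta, pi)."""
    alt = np.asarray(ac.alt_counts, dtype=float)
    tot = np.asarray(ac.totals, dtype=float)
    ll_cg = np.stack([_component_loglik(alt, tot, theta[g])
                      for g in range(2)], axis=1) + np.log(pi)[None, :]
    return float(logsumexp(ll_cg, axis=1).sum())


def label_components_by_cnv(assignments: pd.DataFrame, cnv: CNVProfile
                            ) -> pd.DataFrame:
    """Name the component with higher median aneuploidy score 'tumor'.

    Raises on an exact tie of medians rather than choosing silently.
    """
    assignments = assignments.copy()
    an = pd.Series(cnv.aneuploidy, index=cnv.cell_names)
    med = {}
    for comp in ("A", "B"):
        cells = assignments.loc[assignments["label"] == comp, "barcode"]
        if len(cells) == 0:
            raise ValueError(f"component {comp} has no assigned cells")
        med[comp] = float(an.loc[cells].median())
    if med["A"] == med["B"]:
        raise ValueError("aneuploidy medians tie; cannot label genotypes "
                         "-- label manually")
    tumor = "A" if med["A"] > med["B"] else "B"
    mapping = {tumor: "tumor", ("B" if tumor == "A" else "A"): "organoid"}
    assignments["genotype"] = assignments["label"].map(mapping)
    assignments.attrs["component_genotype"] = mapping
    return assignments


def rescue_unassigned(assignments: pd.DataFrame, adata: ad.AnnData,
                      n_neighbors: int = 30, n_pcs: int = 30,
                      n_hvg: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Assign leftover cells by majority genotype of nearest assigned cells.

    Neighbors are found in ``n_pcs``-dimensional PCA space of the normalized
    expression matrix restricted to highly variable genes.
    """
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    assignments = assignments.copy()
    assigned = assignments["label"] != "unassigned"
    if not assigned.any():
        raise ValueError("no assigned cells to rescue from")
    if assigned.all():
        return assignments

    if n_hvg < adata.n_vars:
        from .qc import select_hvg
        try:
            genes = select_hvg(adata, n_hvg)
            adata = adata[:, genes]
        except ValueError:
            pass
    x = as_dense(adata.X)
    x = x - x.mean(axis=0)
    n_pcs = min(n_pcs, min(x.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)

    order = pd.Index(assignments["barcode"])
    pos = pd.Series(np.arange(adata.n_obs), index=adata.obs_names)
    pcs = pcs[pos.loc[order].to_numpy()]

    idx_assigned = np.where(assigned.to_numpy())[0]
    k = n_neighbors
    if len(idx_assigned) < n_neighbors:
        warnings.warn("fewer assigned cells than n_neighbors; using all")
        k = len(idx_assigned)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs[idx_assigned])
    idx_un = np.where(~assigned.to_numpy())[0]
    _, nbrs = nn.kneighbors(pcs[idx_un])
    labels = assignments["label"].to_numpy(dtype=object)
    geno = assignments["genotype"].to_numpy(dtype=object)
    for row, i in zip(nbrs, idx_un):
        votes = labels[idx_assigned[row]]
        won = pd.Series(votes).mode().iloc[0]
        labels[i] = won
        donor = idx_assigned[row][votes == won][0]
        geno[i] = geno[donor]
        assignments.iloc[i, assignments.columns.get_loc("method")] = \
            "neighbor-rescue"
    assignments["label"] = labels
    assignments["genotype"] = geno
    return assignments


def genotype_fractions(assignments: pd.DataFrame, sample_labels
                       ) -> pd.DataFrame:
    """Per-sample tumor-cell proportion among genotype-labeled cells.

    ``sample_labels``: mapping barcode -> sample (Series or dict). Unassigned
    cells are excluded from the fraction and reported separately.
    """
    sample_labels = pd.Series(sample_labels)
    missing = ~pd.Index(assignments["barcode"]).isin(sample_labels.index)
    if missing.any():
        bad = assignments["barcode"][missing].iloc[0]
        raise ValueError(f"cell {bad!r} has no sample label")
    df = assignments.assign(sample=sample_labels.loc[
        assignments["barcode"]].to_numpy())
    rows = []
    for s, grp in df.groupby("sample", sort=True):
        labeled = grp[grp["label"] != "unassigned"]
        n_tumor = int((labeled["genotype"] == "tumor").sum())
        rows.append({
            "sample": s,
            "n_cells": len(grp),
            "n_labeled": len(labeled),
            "n_tumor": n_tumor,
            "n_unassigned": int((grp["label"] == "unassigned").sum()),
            "tumor_fraction": n_tumor / len(labeled) if len(labeled) else
            np.nan,
        })
    return pd.DataFrame(rows)
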