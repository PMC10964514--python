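"""Readers and writers for the on-disk formats the pipeline consumes.

Expression matrices travel as Matrix Market (genes x cells) with
``genes.tsv`` / ``barcodes.tsv`` sidecars; allele counts and bulk counts as
TSV; genotypes as single-sample VCF v4.2; gene sets as GMT.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import pysam
from scipy import io as spio
from scipy import sparse

from .sim import AlleleCounts, GenotypePair, HET, HOM_ALT, HOM_REF


# ---------------------------------------------------------------------------
# expression matrices


def write_expression(adata: ad.AnnData, outdir: str) -> None:
    """Write counts as MTX (genes x cells) with genes.tsv / barcodes.tsv."""
    os.makedirs(outdir, exist_ok=True)
    x = adata.layers.get("counts", adata.X)
    mat = sparse.csr_matrix(x).T  # genes x cells on disk
    spio.mmwrite(os.path.join(outdir, "matrix.mtx"), mat)
    genes = adata.var[["symbol", "chrom", "pos"]]
    genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    adata.obs.to_csv(os.path.join(outdir, "barcodes.tsv"), sep="\t",
                     index=False)


def read_expression(indir: str) -> ad.AnnData:
    """Read an MTX directory written by :func:`write_expression`."""
    mat = spio.mmread(os.path.join(indir, "matrix.mtx")).tocsr().T
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t")
    obs = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t")
    var = genes.set_index("symbol", drop=False).rename_axis(None)
    obs = obs.set_index("barcode", drop=False).rename_axis(None)
    adata = ad.AnnData(X=mat.astype(np.int32), obs=obs, var=var)
    adata.uns["layer"] = "raw"
    return adata


# ---------------------------------------------------------------------------
# allele counts


def write_allele_counts(acm: AlleleCounts, path: str) -> None:
    """Long-format TSV: barcode, chrom, pos, ref, alt, ref_count, alt_count.

    Only covered (depth > 0) cell-site entries are written.
    """
    cells, sites = np.nonzero(acm.totals)
    df = pd.DataFrame({
        "barcode": np.array(acm.barcodes)[cells],
        "chrom": acm.sites["chrom"].to_numpy()[sites],
        "pos": acm.sites["pos"].to_numpy()[sites],
        "ref": acm.sites["ref"].to_numpy()[sites],
        "alt": acm.sites["alt"].to_numpy()[sites],
        "ref_count": acm.ref_counts[cells, sites],
        "alt_count": acm.alt_counts[cells, sites],
    })
    df.to_csv(path, sep="\t", index=False)


def read_allele_counts(path: str, barcodes: list | None = None) -> AlleleCounts:
    df = pd.read_csv(path, sep="\t")
    sites = (df[["chrom", "pos", "ref", "alt"]].drop_duplicates()
             .sort_values(["chrom", "pos"]).reset_index(drop=True))
    site_key = {t: i for i, t in enumerate(
        sites.itertuples(index=False, name=None))}
    if barcodes is None:
        barcodes = list(pd.unique(df["barcode"]))
    bc_key = {b: i for i, b in enumerate(barcodes)}
    n, s = len(barcodes), len(sites)
    ref = np.zeros((n, s), dtype=np.int32)
    alt = np.zeros((n, s), dtype=np.int32)
    ci = df["barcode"].map(bc_key).to_numpy()
    si = np.array([site_key[t] for t in
                   df[["chrom", "pos", "ref", "alt"]]
                   .itertuples(index=False, name=None)])
    ref[ci, si] = df["ref_count"].to_numpy()
    alt[ci, si] = df["alt_count"].to_numpy()
    return AlleleCounts(sites, ref, alt, list(barcodes))


def write_bulk_counts(bulk: pd.DataFrame, path: str) -> None:
    bulk.to_csv(path, sep="\t", index=False)


def read_bulk_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1"}


def write_genotype_vcfs(pair: GenotypePair, path_a: str, path_b: str,
                        sample_a: str = "genoA", sample_b: str = "genoB",
                        depth: int = 60, qual: float = 100.0) -> None:
    """Write the two genotypes as single-sample VCF v4.2 files with GT/DP."""
    for path, geno, sample in ((path_a, pair.geno_a, sample_a),
                               (path_b, pair.geno_b, sample_b)):
        header = pysam.VariantHeader()
        header.add_line('##fileformat=VCFv4.2')
        for c in sorted(set(pair.sites["chrom"]),
                        key=lambda x: int(str(x).replace("chr", ""))):
            header.contigs.add(str(c), length=60_000_000)
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("DP", 1, "Integer", "Read depth")
        header.add_sample(sample)
        with pysam.VariantFile(path, "w", header=header) as vf:
            for i, row in enumerate(pair.sites.itertuples(index=False)):
                rec = vf.new_record(contig=str(row.chrom), start=row.pos - 1,
                                    alleles=(row.ref, row.alt), qual=qual)
                g = geno[i]
                rec.samples[sample]["GT"] = \
                    (0, 0) if g == HOM_REF else ((0, 1) if g == HET else (1, 1))
                rec.samples[sample]["DP"] = depth
                vf.write(rec)


def read_vcf_calls(path: str) -> pd.DataFrame:
    """Read a single-sample VCF into (chrom, pos, ref, alt, gt, dp, qual).

    ``gt`` is coded 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing/other.
    Multiallelic and non-SNP records are skipped and counted in
    ``df.attrs['n_skipped']``.
    """
    from cyvcf2 import VCF

    rows, skipped = [], 0
    vcf = VCF(path)
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        code = {0: 0, 1: 1, 3: 2}.get(int(v.gt_types[0]), -1)
        try:
            dp = int(v.format("DP")[0][0])
        except (TypeError, KeyError):
            dp = -1
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], code, dp,
                     v.QUAL if v.QUAL is not None else np.inf))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gt",
                                     "dp", "qual"])
    df.attrs["n_skipped"] = skipped
    return df


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str) -> dict:
    """Read a GMT file into {set name: [genes]} (description column dropped)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path: str, description: str = ".") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
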