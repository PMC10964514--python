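"""Mutually exclusive germline SNP fingerprints and bulk mixture detection.

Comparing two genotypes' germline callsets yields, for each genotype, a
panel of sites at which it carries the alternate allele while the other
genotype is confidently homozygous reference. The proportion of a panel
detected in a bulk DNA sample (enough depth, enough alt reads) tracks the
presence of that genotype in the mixture, which is how a rare tumor genotype
is monitored in organoid co-culture DNA over time or across treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import io as gio

_SITE_COLS = ["chrom", "pos", "ref", "alt"]


@dataclass
class FingerprintPanel:
    """Genotype-exclusive SNP sites with the provenance filters applied."""

    panel_a: pd.DataFrame   # chrom, pos, ref, alt, zygosity (het/hom-alt)
    panel_b: pd.DataFrame
    min_depth: int
    min_quality: float
    n_skipped: dict = field(default_factory=dict)

    def panel(self, genotype: str) -> pd.DataFrame:
        return self.panel_a if genotype == "A" else self.panel_b


@dataclass
class MixtureEstimate:
    """Per-genotype fingerprint detection in one bulk sample."""

    sample_id: str
    n_evaluable: dict
    n_detected: dict
    n_absent: dict
    min_depth: int
    min_alt_reads: int

    def detected_fraction(self, genotype: str) -> float | None:
        n_ev = self.n_evaluable[genotype]
        return self.n_detected[genotype] / n_ev if n_ev else None


def _calls_to_frame(calls) -> pd.DataFrame:
    if isinstance(calls, (str, bytes)):
        return gio.read_vcf_calls(calls)
    return calls


def build_fingerprints(callset_a, callset_b, min_depth: int = 10,
                       min_quality: float = 30.0) -> FingerprintPanel:
    """Derive mutually exclusive SNP panels from two germline callsets.

    ``callset_a``/``callset_b``: VCF paths or frames from
    :func:`glicomix.io.read_vcf_calls`. A site enters panel A when genotype A
    is het or hom-alt with quality >= ``min_quality`` and depth >=
    ``min_depth``, and genotype B has an explicit hom-ref call with depth >=
    ``min_depth`` at the same (chrom, pos, ref, alt); symmetrically for B.
    Hom-ref confirmation requires the 0/0 record: absence is not reference.
    """
    a = _calls_to_frame(callset_a)
    b = _calls_to_frame(callset_b)
    contigs_a, contigs_b = set(a["chrom"]), set(b["chrom"])
    if contigs_a and contigs_b and not (contigs_a & contigs_b):
        raise ValueError(
            "contig naming mismatch between callsets: "
            f"{sorted(contigs_a)[:5]} vs {sorted(contigs_b)[:5]}")

    merged = a.merge(b, on=_SITE_COLS, how="outer", suffixes=("_a", "_b"))
    for col in ("gt_a", "gt_b"):
        merged[col] = merged[col].fillna(-1).astype(int)
    for col in ("dp_a", "dp_b"):
        merged[col] = merged[col].fillna(-1).astype(int)
    for col in ("qual_a", "qual_b"):
        merged[col] = merged[col].fillna(-np.inf)

    def _one_side(own: str, other: str) -> pd.DataFrame:
        carry = merged[f"gt_{own}"].isin([1, 2])
        ok = (carry
              & (merged[f"qual_{own}"] >= min_quality)
              & (merged[f"dp_{own}"] >= min_depth)
              & (merged[f"gt_{other}"] == 0)
              & (merged[f"dp_{other}"] >= min_depth))
        out = merged.loc[ok, _SITE_COLS].copy()
        out["zygosity"] = merged.loc[ok, f"gt_{own}"].map(
            {1: "het", 2: "hom-alt"}).to_numpy()
        return out.sort_values(["chrom", "pos"]).reset_index(drop=True)

    skipped = {"a": a.attrs.get("n_skipped", 0),
               "b": b.attrs.get("n_skipped", 0)}
    return FingerprintPanel(_one_side("a", "b"), _one_side("b", "a"),
                            min_depth, min_quality, skipped)


def detect_fingerprints(panel: FingerprintPanel, bulk: pd.DataFrame,
                        min_depth: int = 10, min_alt_reads: int = 3,
                        sample_id: str = "sample") -> MixtureEstimate:
    """Score a bulk allele-count table against both fingerprint panels.

    A panel site is evaluable when present in the bulk table with depth >=
    ``min_depth`` and detected when its alt reads >= ``min_alt_reads``.
    Sites absent from the bulk table are counted as non-evaluable.
    """
    bulk = bulk.copy()
    bulk["depth"] = bulk["ref_count"] + bulk["alt_count"]
    n_ev, n_det, n_abs = {}, {}, {}
    for g in ("A", "B"):
        p = panel.panel(g)
        m = p.merge(bulk, on=_SITE_COLS, how="left")
        present = m["depth"].notna()
        evaluable = present & (m["depth"] >= min_depth)
        detected = evaluable & (m["alt_count"] >= min_alt_reads)
        n_ev[g] = int(evaluable.sum())
        n_det[g] = int(detected.sum())
        n_abs[g] = int((~present).sum())
    return MixtureEstimate(sample_id, n_ev, n_det, n_abs, min_depth,
                           min_alt_reads)


def compare_samples(estimates: list) -> pd.DataFrame:
    """Side-by-side detected fractions per genotype across samples.

    Returns a table with one row per genotype, a column per sample, and
    difference columns relative to the first sample.
    """
    if len(estimates) < 2:
        raise ValueError("need at least 2 estimates to compare")
    ids = [e.sample_id for e in estimates]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated sample ids")
    rows = {}
    for g in ("A", "B"):
        rows[g] = {e.sample_id: e.detected_fraction(g) for e in estimates}
    df = pd.DataFrame(rows).T.rename_axis("genotype")
    base = ids[0]
    for s in ids[1:]:
        df[f"diff_{s}_vs_{base}"] = df[s] - df[base]
    return df.reset_index()


def estimate_mixture_fraction(panel: FingerprintPanel, bulk: pd.DataFrame,
                              error_rate: float = 1e-3) -> float:
    """Maximum-likelihood genotype-B fraction from panel-site allele counts.

    Goes beyond the binary detection readout: models alt counts at each
    panel site as Binomial(depth, f * vaf + error blending) and maximizes
    the joint likelihood over the mixture fraction f of genotype B.
    """
    bulk = bulk.copy()
    bulk["depth"] = bulk["ref_count"] + bulk["alt_count"]
    frames = []
    for g, sign in (("A", -1.0), ("B", 1.0)):
        m = panel.panel(g).merge(bulk, on=_SITE_COLS, how="inner")
        m = m[m["depth"] > 0]
        m["vaf"] = m["zygosity"].map({"het": 0.5, "hom-alt": 1.0})
        m["sign"] = sign
        frames.append(m)
    data = pd.concat(frames, ignore_index=True)
    if data.empty:
        raise ValueError("no covered panel sites in the bulk table")
    depth = data["depth"].to_numpy(float)
    alt = data["alt_count"].to_numpy(float)
    vaf = data["vaf"].to_numpy(float)
    sign = data["sign"].to_numpy(float)

    def negll(f):
        frac = np.where(sign > 0, f, 1.0 - f)
        p = frac * vaf
        p = p * (1 - error_rate) + (1 - p) * error_rate
        return -stats.binom.logpmf(alt, depth, p).sum()

    res = optimize.minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded")
    return float(res.x)
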