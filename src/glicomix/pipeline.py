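"""Orchestration: simulate -> QC -> demultiplex -> fingerprints -> scores ->
staging -> crosstalk, driven by a validated configuration.

The pipeline runs on a fully synthetic experiment with known ground truth.
Each enabled stage contributes a section to a machine-readable JSON report;
output is written atomically (temp file, renamed on success).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
import tempfile

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import cnv as cnv_mod
from . import crosstalk as ct
from . import demux as dx
from . import fingerprint as fp
from . import io as gio
from . import qc
from . import scoring as sc
from . import sim
from . import staging as st

log = logging.getLogger("glicomix")


class ConfigError(ValueError):
    """Raised for schema violations in the run configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Strict):
    n_cells: int = 2000
    n_genes: int = 2000
    n_snps: int = 200
    tumor_fraction: float = 0.1
    exclusive_fraction: float = 0.1
    mean_reads_per_cell_at_snps: float = 20.0
    error_rate: float = 1e-3
    bulk_fractions: list[float] = Field(default=[0.01, 0.3])
    bulk_mean_depth: float = 100.0
    reference_ages: list[int] = Field(default=[4, 8, 12, 16, 20, 24])
    reference_replicates: int = 3


class QCSection(_Strict):
    min_genes: int = 750
    max_mito: float = 0.10
    min_cells: int = 5
    target_sum: float = 10_000.0


class DemuxSection(_Strict):
    posterior_threshold: float = 0.99
    error_rate: float = 1e-3
    n_neighbors: int = 30
    window_genes: int = 101


class FingerprintSection(_Strict):
    min_depth: int = 10
    min_alt_reads: int = 3
    min_quality: float = 30.0


class ScoreSection(_Strict):
    n_bins: int = 24
    n_ctrl_per_gene: int = 100


class CrosstalkSection(_Strict):
    n_permutations: int = 1000
    min_expressed_fraction: float = 0.10
    alpha: float = 0.05


class StagesSection(_Strict):
    qc: bool = True
    demux: bool = True
    fingerprint: bool = True
    score: bool = True
    stage: bool = True
    crosstalk: bool = True


class RunConfig(_Strict):
    seed: int = 0
    outdir: str = "glicomix_out"
    samples: list[str] = Field(default=["S1"])
    sim: SimSection = SimSection()
    qc: QCSection = QCSection()
    demux: DemuxSection = DemuxSection()
    fingerprint: FingerprintSection = FingerprintSection()
    score: ScoreSection = ScoreSection()
    crosstalk: CrosstalkSection = CrosstalkSection()
    stages: StagesSection = StagesSection()

    @field_validator("seed")
    @classmethod
    def _seed_nonneg(cls, v):
        if v < 0:
            raise ValueError("seed must be non-negative")
        return v

    @field_validator("samples")
    @classmethod
    def _samples_nonempty(cls, v):
        if not v:
            raise ValueError("sample list must be non-empty")
        return v


def validate_config(path: str) -> RunConfig:
    """Parse and schema-check a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries field paths
        raise ConfigError(str(exc)) from exc


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages on a synthetic experiment; return report."""
    rng = np.random.default_rng(cfg.seed)
    report = {"config_hash": config_hash(cfg), "seed": cfg.seed}

    log.info("simulate: %d cells, %d genes, %d SNPs",
             cfg.sim.n_cells, cfg.sim.n_genes, cfg.sim.n_snps)
    pair = sim.make_genotypes(cfg.sim.n_snps, cfg.sim.exclusive_fraction,
                              seed=cfg.seed)
    simcfg = sim.default_config(
        n_cells=cfg.sim.n_cells, n_genes=cfg.sim.n_genes,
        n_snps=cfg.sim.n_snps, tumor_fraction=cfg.sim.tumor_fraction,
        mean_reads_per_cell_at_snps=cfg.sim.mean_reads_per_cell_at_snps,
        error_rate=cfg.sim.error_rate, seed=cfg.seed + 1)
    adata, acm, truth = sim.simulate_cells(pair, simcfg)
    # spread cells over the configured samples for per-sample summaries
    samples = np.array(cfg.samples)[
        rng.integers(0, len(cfg.samples), size=adata.n_obs)]
    adata.obs["sample"] = samples
    report["simulate"] = {"n_cells": adata.n_obs, "n_genes": adata.n_vars,
                          "tumor_fraction_true":
                          truth.tumor_fraction_realized}

    if cfg.stages.qc:
        n0 = adata.n_obs
        adata = qc.filter_cells(adata, cfg.qc.min_genes, cfg.qc.max_mito)
        adata = qc.filter_genes(adata, cfg.qc.min_cells)
        log.info("qc: %d -> %d cells, %d genes kept", n0, adata.n_obs,
                 adata.n_vars)
        report["qc"] = {"cells_before": n0, "cells_after": adata.n_obs,
                        "genes_after": adata.n_vars}
    norm = qc.normalize(adata, cfg.qc.target_sum)

    if cfg.stages.demux:
        keep = [acm.barcodes.index(b) for b in norm.obs_names]
        acm_f = sim.AlleleCounts(acm.sites, acm.ref_counts[keep],
                                 acm.alt_counts[keep],
                                 [acm.barcodes[i] for i in keep])
        assign, _ = dx.fit_two_genotype_mixture(
            acm_f, error_rate=cfg.demux.error_rate,
            posterior_threshold=cfg.demux.posterior_threshold, seed=cfg.seed)
        ref_mask = (assign["label"] == assign.loc[
            assign["label"] != "unassigned", "label"].value_counts()
            .idxmax()).to_numpy()
        profile = cnv_mod.infer_cnv(norm, ref_mask, cfg.demux.window_genes)
        assign = dx.label_components_by_cnv(assign, profile)
        n_unassigned = int((assign["label"] == "unassigned").sum())
        assign = dx.rescue_unassigned(assign, norm, cfg.demux.n_neighbors,
                                      seed=cfg.seed)
        fractions = dx.genotype_fractions(
            assign, pd.Series(norm.obs["sample"].to_numpy(),
                              index=norm.obs_names))
        truth_lab = norm.obs["true_genotype"].to_numpy()
        pred = np.where(assign["genotype"].to_numpy() == "tumor", "B", "A")
        acc = float((pred == truth_lab).mean())
        report["demux"] = {
            "n_unassigned_mixture": n_unassigned,
            "pct_assigned_mixture":
                100.0 * (1 - n_unassigned / len(assign)),
            "accuracy_vs_truth": acc,
            "fractions": fractions.to_dict(orient="records"),
        }
        norm.obs["genotype"] = assign.set_index("barcode")["genotype"] \
            .loc[norm.obs_names].to_numpy()

    if cfg.stages.fingerprint:
        with tempfile.TemporaryDirectory() as td:
            va, vb = os.path.join(td, "a.vcf"), os.path.join(td, "b.vcf")
            gio.write_genotype_vcfs(pair, va, vb)
            panel = fp.build_fingerprints(
                va, vb, cfg.fingerprint.min_depth, cfg.fingerprint.min_quality)
        ests = []
        for i, f in enumerate(cfg.sim.bulk_fractions):
            bulk, _ = sim.simulate_bulk_mixture(
                pair, f, cfg.sim.bulk_mean_depth, cfg.sim.error_rate,
                seed=cfg.seed + 100 + i)
            ests.append(fp.detect_fingerprints(
                panel, bulk, cfg.fingerprint.min_depth,
                cfg.fingerprint.min_alt_reads, sample_id=f"bulk_{f}"))
        report["fingerprint"] = {
            e.sample_id: {"A": e.detected_fraction("A"),
                          "B": e.detected_fraction("B")} for e in ests}

    if cfg.stages.score:
        # score each cell type's marker module; groups = cell type
        sets = []
        for ctype in simcfg.cell_types:
            genes = tuple(g for g in
                          (f"G{j:05d}" for j in ctype.marker_genes)
                          if g in norm.var_names)
            if genes:
                sets.append(sc.GeneSet(ctype.name + "_markers", genes))
        scores = pd.DataFrame({
            s.name: sc.module_score(norm, s, cfg.score.n_bins,
                                    cfg.score.n_ctrl_per_gene, cfg.seed)
            for s in sets})
        summary = sc.scaled_group_summary(
            scores, norm.obs["cell_type"].to_numpy())
        report["score"] = {"scaled_group_means": summary.round(4).to_dict()}

    if cfg.stages.stage:
        ages = [a for a in cfg.sim.reference_ages
                for _ in range(cfg.sim.reference_replicates)]
        ref = sim.simulate_reference_series(ages, n_genes=cfg.sim.n_genes,
                                            seed=cfg.seed + 7)
        pb = st.pseudobulk(norm, norm.obs["sample"].to_numpy())
        staged = st.stage_by_correlation(
            pb, ref, n_hvg=min(2000, len(pb.index.intersection(
                ref.expr.index))))
        report["stage"] = {"best_age": staged["best_age"].to_dict()}

    if cfg.stages.crosstalk:
        pairs = default_lr_pairs(norm, simcfg)
        sub, labels = ct.prepare_crosstalk_input(
            norm, norm.obs["cell_type"].to_numpy(), n_hvg=norm.n_vars,
            pairs=pairs)
        res = ct.lr_permutation_test(
            sub, labels, pairs, cfg.crosstalk.n_permutations,
            cfg.crosstalk.min_expressed_fraction, cfg.crosstalk.alpha,
            seed=cfg.seed)
        counts = ct.interaction_counts(res)
        report["crosstalk"] = {"counts": counts.to_dict(),
                               "n_significant":
                               int(res.table["significant"].sum())}
    return report


def default_lr_pairs(adata, simcfg) -> list:
    """Toy LR pairs from simulated marker modules (ligand in one cell type's
    module, receptor in another's) so crosstalk runs end-to-end on synthetic
    gene names."""
    pairs = []
    cts = simcfg.cell_types
    for i, ct_a in enumerate(cts):
        ct_b = cts[(i + 1) % len(cts)]
        la = [g for g in (f"G{j:05d}" for j in ct_a.marker_genes)
              if g in adata.var_names]
        rb = [g for g in (f"G{j:05d}" for j in ct_b.marker_genes)
              if g in adata.var_names]
        if la and rb:
            pairs.append(ct.LRPair(f"{ct_a.name}_to_{ct_b.name}",
                                   (la[0],), (rb[0],)))
    return pairs


def write_report(report: dict, outdir: str) -> str:
    """Atomically write the JSON report into ``outdir``; return its path."""
    os.makedirs(outdir, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=outdir, suffix=".json.tmp")
    with os.fdopen(fd, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    final = os.path.join(outdir, "report.json")
    shutil.move(tmp, final)
    return final
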