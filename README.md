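# glicomix

Analysis toolkit for **two-genotype tumor/organoid co-cultures profiled by
droplet single-cell RNA-seq**, with a fully synthetic data generator so
every method can be validated against known ground truth.

The scientific setting: a rare glioma-stem-cell genotype is seeded into
stem-cell-derived cerebral organoids and the mixture is sequenced over
time. The computational problems that creates, all covered here:

- **Genotype demultiplexing** (`glicomix.demux`) — assign each droplet to
  tumor or organoid genotype from sparse SNP allele counts, without a
  genotype reference: a two-component binomial mixture fit by EM with
  per-site alt probabilities restricted to diploid states
  {ε, 0.5, 1−ε}, a 0.99-posterior assignment threshold, component naming
  by inferred-CNV aneuploidy (`glicomix.cnv`), and nearest-neighbor rescue
  of the remaining cells in expression PCA space.
- **Germline SNP fingerprints** (`glicomix.fingerprint`) — mutually
  exclusive variant panels from two VCF callsets and their detection in
  bulk DNA allele counts, including a maximum-likelihood mixture-fraction
  estimator.
- **QC / normalization / markers** (`glicomix.qc`) — droplet QC filters,
  library-size normalization, VST highly-variable-gene selection and
  one-vs-rest Wilcoxon markers (exact for small groups).
- **Signature scoring** (`glicomix.scoring`) — module scores against
  expression-bin-matched control genes, z-scaled group summaries and a
  tie-safe exact rank-sum test.
- **Developmental staging** (`glicomix.staging`) — pseudo-bulk Pearson
  correlation against an age-graded reference, plus cluster specificity
  scores and cross-dataset cluster correlation.
- **Receptor–ligand crosstalk** (`glicomix.crosstalk`) — cluster-label
  permutation test of ligand/receptor co-expression with an
  expressed-fraction gate, interaction counting and a directional
  microenvironment→tumor filter.
- **Simulation** (`glicomix.sim`) — deterministic generators for
  genotypes, single-cell counts with cell types + tumor CNVs, sparse SNP
  coverage, bulk DNA mixtures and an age-graded bulk reference series.
- **Pipeline + CLI** (`glicomix.pipeline`, `glicomix` command) — a
  validated YAML-configured end-to-end run writing a JSON report.

## Worked example

```python
import numpy as np
from glicomix import sim, qc, demux, cnv

# a 2000-cell co-culture, 10% tumor genotype, 200 SNPs (10% exclusive each)
pair = sim.make_genotypes(n_snps=200, exclusive_fraction_per_genotype=0.1,
                          seed=1)
cfg = sim.default_config(n_cells=2000, tumor_fraction=0.1, seed=1)
adata, allele_counts, truth = sim.simulate_cells(pair, cfg)

# stage 1: genotype mixture model on SNP allele counts
assign, theta = demux.fit_two_genotype_mixture(allele_counts, seed=1)
print(assign["label"].value_counts().to_dict())
# {'A': 1469, 'unassigned': 390, 'B': 141}

# stage 2: name components by inferred-CNV aneuploidy, rescue the rest
norm = qc.normalize(adata)
major = assign.loc[assign["label"] != "unassigned", "label"] \
    .value_counts().idxmax()
profile = cnv.infer_cnv(norm, (assign["label"] == major).to_numpy())
assign = demux.label_components_by_cnv(assign, profile)
assign = demux.rescue_unassigned(assign, norm, seed=1)
print(assign["genotype"].value_counts().to_dict())
# {'organoid': 1811, 'tumor': 189}

pred = np.where(assign["genotype"] == "tumor", "B", "A")
print((pred == truth.genotype_labels).mean())
# 1.0
```

At a mean of 20 SNP-covering reads per cell, roughly one cell in five has
too little genotype-discriminating evidence for a 0.99 posterior — that is
an information floor of the coverage, not a fitting failure (the oracle
with the true genotypes does no better). The expression-space rescue
closes the gap because the tumor's copy-number signal separates the two
genotypes almost perfectly; final accuracy above is 100%.

The same chain is available from the shell:

```bash
glicomix simulate --seed 1 --outdir sim_out
glicomix demux sim_out/allele_counts.tsv --out assign.tsv
glicomix cnv sim_out assign.tsv --out labeled.tsv
glicomix run --config config.yaml   # full pipeline, JSON report
```

## Layout

```
src/glicomix/      library (sim, io, qc, cnv, demux, fingerprint,
                   scoring, staging, crosstalk, pipeline, cli)
src/glicomix/data/ packaged ligand-receptor pairs and example signatures
tests/             pytest suite incl. acceptance criteria
scripts/           acceptance readout script
docs/methods.md    model and parameter documentation
```
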