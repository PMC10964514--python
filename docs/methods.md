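# Methods

Models, assumptions and parameter choices behind each module. All default
problem sizes are the package's own desk-scale choices; everything runs in
seconds to a couple of minutes on one CPU.

## 1. Synthetic data generator (`glicomix.sim`)

The generator emulates the statistical structure of a two-genotype
tumor/organoid co-culture; it does not attempt biological realism beyond
what the downstream methods consume.

**Genotypes.** A biallelic SNP panel (default 200 sites) spread uniformly
over 22 autosomes. Each genotype receives `round(f·n_snps)` private
("exclusive") alt-carrying sites (default f = 0.1 per genotype; het with
probability 0.7, hom-alt 0.3), hom-ref in the other genotype; all other
sites carry identical genotypes drawn with probabilities (¼, ½, ¼) for
hom-ref/het/hom-alt. Rationale: only exclusive sites are informative for
demultiplexing; shared sites act as realistic distractors.

**Cells.** Each cell is tumor ("B") with the configured probability
(default 0.1) and draws a cell type from four defaults (proportions
0.35/0.30/0.20/0.15) whose disjoint marker modules (n_genes/50 genes
each) are upregulated 4-fold. Tumor cells additionally scale two
chromosome-segment blocks of the genomically ordered genes (gain ×2 over
the 25–40% quantile range, loss ×0.5 over 60–72%), which is the signal the
CNV labeler uses. Expression is negative binomial (gamma–Poisson,
dispersion 0.1) around these means with lognormal library sizes
(meanlog 8.5, sdlog 0.35 → median ~4900 counts/cell).

**SNP coverage.** Per cell, Poisson(20) reads spread multinomially over
sites; each read reports alt with probability `vaf·(1−e) + (1−vaf)·e`,
e = 10⁻³. This mirrors the sparse, shallow coverage of droplet data: most
cell-site pairs have 0 reads.

**Bulk mixtures.** Per site, depth ~ Poisson(mean_depth), alt ~
Binomial(depth, mixture-weighted VAF blended with e).

**Reference series.** Bulk count profiles over an age grid: lognormal
baseline abundances, one 50-gene module per age whose expression peaks at
that age and decays with a Gaussian kernel in age rank (amplitude 2,
width 0.75), NB noise. This gives staging a recoverable but noisy signal.

**Omitted on purpose:** doublets/ambient RNA, batch effects, subclonal
CNVs, transcriptional similarity between the two genotypes' programs
beyond the shared baseline, and sequencing-depth gradients.

## 2. QC and normalization (`glicomix.qc`)

Cells: ≥ 750 detected genes and ≤ 10% mitochondrial counts (symbols
`MT-*`). Genes: detected in ≥ 5 cells; ribosomal (`RPL*/RPS*`) dropped.
Normalization: `log1p(count / cell_total × 10,000)`; raw counts kept in
`layers["counts"]`, and `expm1` of a normalized row sums back to the
target (tested identity).

**HVG selection** uses standardized variance after a variance-stabilizing
trend: fit log10(variance) on log10(mean) with a degree-2 polynomial over
genes with positive mean and variance, standardize counts by the trend's
expected SD, clip at √n_cells, rank genes by the variance of the clipped
values. A polynomial replaces the usual loess fit; at desk scale the two
rank genes nearly identically and the polynomial has no extra dependency.

**Markers**: one-vs-rest two-sided Wilcoxon rank-sum per cluster, exact by
full enumeration when ≤ 50 cells total (tie-safe midranks), tie-corrected
normal approximation otherwise; Benjamini–Hochberg adjustment within each
cluster; log2 fold changes on expm1-backtransformed means.

## 3. Genotype demultiplexing (`glicomix.demux`, `glicomix.cnv`)

Two-component binomial mixture over per-cell alt/total counts. Each
component's per-site alt probability θ is restricted to the diploid states
{ε, 0.5, 1−ε} (ε = max(error_rate, 10⁻⁶)); the M-step picks the ML state
from responsibility-weighted counts. Initialization: five k-means++
bipartitions of the zero-imputed alt-fraction vectors (plus every hard
bipartition when ≤ 10 cells, making tiny instances exactly solvable).
After EM converges, θ is refit from hard MAP assignments and iterated
while the observed-data likelihood improves; this escapes the local optima
that soft responsibilities create when a 9:1 majority leaks weight into
the minority's site counts. Cells with max posterior ≥ 0.99 are assigned;
zero-coverage cells are always unassigned.

Component → tumor/organoid naming uses inferred CNV: genes in genomic
order, normalized expression centered on the majority component, 101-gene
moving average within each chromosome (window truncated with a warning on
shorter chromosomes), per-cell aneuploidy = mean squared window score; the
component with higher median aneuploidy is the tumor, an exact tie raises.

Unassigned cells are rescued by the majority genotype among their 30
nearest assigned neighbors in 30-PC PCA space of the HVG-restricted
normalized matrix.

**Coverage limits.** With 20 reads/cell and 20% of sites exclusive, a
cell sees ~1.9 genotype-discriminating reads on average, so ~15–20% of
cells cannot reach a 0.99 posterior regardless of fit quality (an oracle
given the true θ does no better). The rescue stage exists precisely for
this regime, and final accuracy on the default simulation is 1.00.

## 4. SNP fingerprints (`glicomix.fingerprint`)

A site enters genotype X's panel when X is het/hom-alt with QUAL ≥ 30 and
DP ≥ 10 **and** the other genotype has an explicit 0/0 call with DP ≥ 10
at the same (chrom, pos, ref, alt) — absence of a record is never treated
as reference. Detection in bulk: a panel site is evaluable at depth ≥ 10
and detected at ≥ 3 alt reads; detected fraction = detected/evaluable
(None when nothing is evaluable). Detection per site is
Bernoulli(P[Bin(depth, p_alt) ≥ 3]) — tested against that closed form.
`estimate_mixture_fraction` goes further and maximizes the joint binomial
likelihood over the mixture fraction using both panels' zygosities.

## 5. Signature scoring (`glicomix.scoring`)

Genes are ranked by mean expression into 24 bins; for each signature gene,
100 control genes are drawn with replacement from its bin and pooled;
score = mean(signature) − mean(control pool). Binning makes the null
expectation 0 irrespective of the signature's expression level (the
all-genes set scores ≈ 0, tested). Group summaries are z-scaled across
group means per signature (single group → 0 with a warning; zero SD → 0).
The exact rank test enumerates all group-1 subsets with midranks; the
two-sided p is the fraction of subsets whose rank sum is at least as far
from expectation as observed (4v4 perfect separation → 2/70 ≈ 0.0286);
above 20 total observations it switches to the tie-corrected normal
approximation.

## 6. Staging and specificity (`glicomix.staging`)

Pseudo-bulk = per-sample raw count sums. Staging: variable genes selected
on the **reference only** (so the query cannot steer gene choice), both
sides CPM + log1p, Pearson correlation of each query against each
reference sample, averaged within reference age groups; `best_age` is the
argmax. Specificity score = cluster mean CP10K / global mean CP10K on the
linear scale, giving two identities: a uniformly expressed gene scores
exactly 1 everywhere, and the cell-count-weighted mean over clusters is 1
for every gene. Cross-dataset comparison correlates specificity profiles
over the shared marker genes (≥ 3 required; constant profiles → NaN).

## 7. Receptor–ligand crosstalk (`glicomix.crosstalk`)

Input: cells restricted to the top 5000 HVGs plus all ligand/receptor
genes. For ordered cluster pair (A, B) and pair p, score =
½·(ligand mean in A + receptor mean in B), multi-gene complexes taking the
minimum member mean. Null: recompute under random permutations of the
cluster labels (default 1000); p = (1 + #{null ≥ observed})/(n + 1),
floored at 1/(n+1). A result also requires ≥ 10% expressing cells for the
ligand in A and the receptor in B, and a positive observed score; pairs
referencing absent genes are skipped and recorded. Under the null the
rejection rate matches alpha (tested over ≥ 500 tests). Summaries:
significant-interaction counts per ordered cluster pair (optionally
symmetrized) and a directional filter keeping microenvironment-ligand →
tumor-receptor edges.

## 8. Pipeline and CLI (`glicomix.pipeline`, `glicomix.cli`)

A pydantic-validated YAML config (`extra="forbid"`, so typos fail fast
with exit code 2) drives simulate → QC → demux (+CNV labeling + rescue +
per-sample fractions) → fingerprints (via temporary VCFs) → marker-module
scores → staging against a simulated reference → crosstalk. The JSON
report includes a 16-hex config hash and is written atomically (temp file
+ rename). Data errors exit 3. Default-size end-to-end runs take well
under a minute.

## 9. Numerical / reproducibility notes

- Every stochastic routine takes an explicit seed; all sub-streams derive
  from it. Reports and assignments are bit-reproducible per seed.
- EM log-likelihoods are computed in log space with `logsumexp`; binomial
  coefficients cancel between components and are omitted consistently.
- SNP position sampling uses a unique-integer sampler instead of
  permuting a 50M-element range (pure performance; distribution of
  distinct uniform positions is unchanged).
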