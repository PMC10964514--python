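"""Synthetic two-genotype organoid co-culture data with known ground truth.

The generator emulates the statistical structure of a glioma-stem-cell /
cerebral-organoid co-culture experiment: two diploid genotypes that share
most of their germline SNPs but each carry a private ("exclusive") subset,
a rare tumor genotype mixed into a majority organoid genotype, tumor-specific
chromosome-segment copy-number changes that scale RNA output, cell-type
structure expressed through marker-gene modules, over-dispersed counts with
per-cell library-size variation, sparse per-cell read coverage at SNP sites,
bulk DNA allele counts of genotype mixtures, and an age-graded bulk reference
expression series for developmental staging.

Every generator is deterministic given its seed; all sub-streams are derived
from a single top-level seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd

# diploid genotype codes
HOM_REF, HET, HOM_ALT = 0, 1, 2
_VAF = np.array([0.0, 0.5, 1.0])
_BASES = np.array(list("ACGT"))


def _unique_positions(rng: np.random.Generator, k: int,
                      span: int = 50_000_000) -> np.ndarray:
    """k distinct sorted 1-based positions in [1, span]."""
    pos = np.unique(rng.integers(1, span + 1, size=2 * k + 8))
    while len(pos) < k:  # vanishingly unlikely for k << span
        pos = np.unique(np.concatenate(
            [pos, rng.integers(1, span + 1, size=2 * k)]))
    return np.sort(rng.choice(pos, size=k, replace=False))


# ---------------------------------------------------------------------------
# genotypes


@dataclass(frozen=True)
class GenotypePair:
    """Two diploid genotypes over a shared biallelic SNP panel.

    ``sites`` holds (chrom, pos, ref, alt); ``geno_a``/``geno_b`` are coded
    0 = hom-ref, 1 = het, 2 = hom-alt. ``exclusive_a`` indexes sites that are
    alt-carrying in genotype A and hom-ref in B (symmetrically for B); all
    other sites carry identical genotypes in both.
    """

    sites: pd.DataFrame
    geno_a: np.ndarray
    geno_b: np.ndarray
    exclusive_a: np.ndarray
    exclusive_b: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def vaf(self, which: str) -> np.ndarray:
        """Expected alt-allele fraction per site for genotype 'A' or 'B'."""
        g = self.geno_a if which == "A" else self.geno_b
        return _VAF[g]


def make_genotypes(n_snps: int, exclusive_fraction_per_genotype: float = 0.1,
                   seed: int = 0, het_fraction_exclusive: float = 0.7) -> GenotypePair:
    """Draw a germline SNP panel with mutually exclusive private sites.

    Each genotype receives ``round(exclusive_fraction_per_genotype * n_snps)``
    private alt-carrying sites (het with probability
    ``het_fraction_exclusive``, otherwise hom-alt) at which the other genotype
    is hom-ref; the remaining sites are copied identically between genotypes.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    f = exclusive_fraction_per_genotype
    if not 0 < f <= 0.5:
        raise ValueError("exclusive_fraction_per_genotype must be in (0, 0.5]")
    n_excl = int(round(f * n_snps))
    if 2 * n_excl > n_snps:
        raise ValueError("exclusive sets exceed the panel size")
    rng = np.random.default_rng(seed)

    # sites spread over 22 autosomes in genomic order
    chrom_idx = np.sort(rng.integers(1, 23, size=n_snps))
    pos = np.empty(n_snps, dtype=int)
    for c in range(1, 23):
        m = chrom_idx == c
        pos[m] = _unique_positions(rng, int(m.sum()))
    ref_i = rng.integers(0, 4, size=n_snps)
    alt_i = (ref_i + rng.integers(1, 4, size=n_snps)) % 4
    sites = pd.DataFrame({
        "chrom": [f"chr{c}" for c in chrom_idx],
        "pos": pos,
        "ref": _BASES[ref_i],
        "alt": _BASES[alt_i],
    })

    perm = rng.permutation(n_snps)
    excl_a = np.sort(perm[:n_excl])
    excl_b = np.sort(perm[n_excl:2 * n_excl])

    shared = rng.choice([HOM_REF, HET, HOM_ALT], size=n_snps,
                        p=[0.25, 0.5, 0.25])
    geno_a = shared.copy()
    geno_b = shared.copy()
    p_het = het_fraction_exclusive
    geno_a[excl_a] = rng.choice([HET, HOM_ALT], size=n_excl, p=[p_het, 1 - p_het])
    geno_b[excl_a] = HOM_REF
    geno_b[excl_b] = rng.choice([HET, HOM_ALT], size=n_excl, p=[p_het, 1 - p_het])
    geno_a[excl_b] = HOM_REF
    return GenotypePair(sites, geno_a, geno_b, excl_a, excl_b)


# ---------------------------------------------------------------------------
# single-cell simulation


@dataclass(frozen=True)
class CellType:
    name: str
    proportion: float
    marker_genes: tuple  # gene indices
    fold_change: float = 4.0


@dataclass(frozen=True)
class CNVSegment:
    chrom: str
    start_gene: int  # index into genomic gene order, inclusive
    end_gene: int    # exclusive
    copy_ratio: float


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the single-cell co-culture simulation.

    Defaults give a desk-scale dataset: 2000 cells of which 10% carry the
    tumor genotype, 2000 genes over 22 chromosomes, four cell types defined
    by disjoint 40-gene marker modules, two tumor-private copy-number
    segments (a gain and a loss), 200 SNPs with a mean of 20 SNP-covering
    reads per cell, and a 0.1% per-base miscall rate.
    """

    n_cells: int = 2000
    tumor_fraction: float = 0.1
    n_genes: int = 2000
    cell_types: tuple = ()
    cnv_segments: tuple = ()
    n_snps: int = 200
    mean_reads_per_cell_at_snps: float = 20.0
    error_rate: float = 1e-3
    library_size_lognormal: tuple = (8.5, 0.35)
    dispersion: float = 0.1
    sample_label: str = "S1"
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.mean_reads_per_cell_at_snps <= 0:
            raise ValueError("mean_reads_per_cell_at_snps must be positive")
        if self.cell_types:
            tot = sum(ct.proportion for ct in self.cell_types)
            if abs(tot - 1.0) > 1e-8:
                raise ValueError("cell-type proportions must sum to 1")
        for seg in self.cnv_segments:
            if seg.copy_ratio <= 0:
                raise ValueError("copy ratio must be positive")


def default_config(**overrides) -> SimConfig:
    """The default simulation configuration with standard cell types and CNVs."""
    cfg = SimConfig(**{k: v for k, v in overrides.items()
                       if k not in ("cell_types", "cnv_segments")})
    n_genes = cfg.n_genes
    if "cell_types" in overrides:
        cell_types = overrides["cell_types"]
    else:
        names = ["RadialGlia", "Neuron", "Astrocyte", "InNPC"]
        props = [0.35, 0.3, 0.2, 0.15]
        n_mark = max(5, n_genes // 50)
        cell_types = tuple(
            CellType(nm, pr, tuple(range(i * n_mark, (i + 1) * n_mark)), 4.0)
            for i, (nm, pr) in enumerate(zip(names, props))
        )
    if "cnv_segments" in overrides:
        cnv_segments = overrides["cnv_segments"]
    else:
        # a broad gain and a broad loss, indexed on genomic gene order
        a0, a1 = int(n_genes * 0.25), int(n_genes * 0.40)
        b0, b1 = int(n_genes * 0.60), int(n_genes * 0.72)
        cnv_segments = (CNVSegment("*", a0, a1, 2.0),
                        CNVSegment("*", b0, b1, 0.5))
    return replace(cfg, cell_types=tuple(cell_types),
                   cnv_segments=tuple(cnv_segments))


@dataclass
class SyntheticTruth:
    """Ground-truth labels recorded by the generators."""

    genotype_labels: np.ndarray | None = None   # per cell, 'A' (organoid) / 'B' (tumor)
    cell_type_labels: np.ndarray | None = None
    bulk_fraction_b: float | None = None
    cnv_segments: tuple = ()
    genotypes: GenotypePair | None = None
    config: SimConfig | None = None

    @property
    def tumor_fraction_realized(self) -> float:
        return float(np.mean(self.genotype_labels == "B"))


def _gene_table(n_genes: int, rng: np.random.Generator) -> pd.DataFrame:
    """Gene metadata: symbols and genomic coordinates over 22 autosomes."""
    per = np.full(22, n_genes // 22)
    per[: n_genes - per.sum()] += 1
    chrom = np.repeat([f"chr{c}" for c in range(1, 23)], per)
    pos = np.concatenate([_unique_positions(rng, int(k)) for k in per])
    return pd.DataFrame({
        "symbol": [f"G{i:05d}" for i in range(n_genes)],
        "chrom": chrom, "pos": pos,
        "mito": False, "ribo": False,
    }).set_index("symbol", drop=False).rename_axis(None)


@dataclass
class AlleleCounts:
    """Per-cell ref/alt read counts at biallelic SNP sites."""

    sites: pd.DataFrame          # chrom, pos, ref, alt
    ref_counts: np.ndarray       # cells x sites
    alt_counts: np.ndarray       # cells x sites
    barcodes: list

    @property
    def totals(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts


def simulate_cells(genotypes: GenotypePair, config: SimConfig
                   ) -> tuple[ad.AnnData, AlleleCounts, SyntheticTruth]:
    """Simulate expression counts and SNP allele counts for a cell mixture.

    Expression is negative binomial around cell-type- and CNV-modulated gene
    means with per-cell lognormal library sizes. Per cell, a Poisson number
    of SNP-covering reads is spread uniformly (multinomial) over sites, and
    each read reports the alt allele with probability equal to the cell
    genotype's expected alt fraction blended with the per-base error rate.
    """
    if genotypes.n_sites < 1:
        raise ValueError("genotypes carry no SNP sites")
    if genotypes.n_sites != config.n_snps:
        config = replace(config, n_snps=genotypes.n_sites)
    rng = np.random.default_rng(config.seed)
    n, g = config.n_cells, config.n_genes

    is_tumor = rng.random(n) < config.tumor_fraction
    geno_lab = np.where(is_tumor, "B", "A")

    cts = config.cell_types or (CellType("cell", 1.0, ()),)
    props = np.array([ct.proportion for ct in cts])
    ct_idx = rng.choice(len(cts), size=n, p=props)
    ct_lab = np.array([cts[i].name for i in ct_idx])

    var = _gene_table(g, rng)
    base = np.exp(rng.normal(-1.0, 1.0, size=g))  # relative gene abundances

    # per-cell mean matrix in relative units
    mean = np.tile(base, (n, 1))
    for i, ct in enumerate(cts):
        if len(ct.marker_genes):
            rows = ct_idx == i
            mean[np.ix_(rows, np.array(ct.marker_genes))] *= ct.fold_change
    order = np.arange(g)  # gene table already in genomic order
    for seg in config.cnv_segments:
        genes = order[seg.start_gene:seg.end_gene]
        mean[np.ix_(is_tumor, genes)] *= seg.copy_ratio

    lib = np.exp(rng.normal(*config.library_size_lognormal, size=n))
    mean *= (lib / mean.sum(axis=1))[:, None]

    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mean / shape)
    else:
        lam = mean
    counts = rng.poisson(lam)

    barcodes = [f"BC{i:05d}" for i in range(n)]
    adata = ad.AnnData(
        X=counts.astype(np.int32),
        obs=pd.DataFrame({"barcode": barcodes,
                          "sample": config.sample_label,
                          "true_genotype": geno_lab,
                          "cell_type": ct_lab}, index=barcodes),
        var=var,
    )
    adata.uns["layer"] = "raw"

    # SNP allele counts
    s = genotypes.n_sites
    totals = rng.poisson(config.mean_reads_per_cell_at_snps, size=n)
    if s > 1:
        depth = rng.multinomial(totals, np.full(s, 1.0 / s))
    else:
        depth = totals[:, None]
    vaf = np.where(is_tumor[:, None], genotypes.vaf("B")[None, :],
                   genotypes.vaf("A")[None, :])
    e = config.error_rate
    p_alt = vaf * (1 - e) + (1 - vaf) * e
    alt = rng.binomial(depth, p_alt)
    acm = AlleleCounts(genotypes.sites.copy(), (depth - alt).astype(np.int32),
                       alt.astype(np.int32), barcodes)

    truth = SyntheticTruth(geno_lab, ct_lab, None, config.cnv_segments,
                           genotypes, config)
    return adata, acm, truth


# ---------------------------------------------------------------------------
# bulk WES mixture


def simulate_bulk_mixture(genotypes: GenotypePair, fraction_b: float,
                          mean_depth: float = 100.0, error_rate: float = 1e-3,
                          seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Bulk allele counts at the SNP panel for a two-genotype DNA mixture.

    Per site, depth ~ Poisson(mean_depth) and alt reads ~ Binomial(depth, p)
    with p the mixture-weighted alt fraction blended with the error rate.
    Returns a table (chrom, pos, ref, alt, ref_count, alt_count).
    """
    if not 0 <= fraction_b <= 1:
        raise ValueError("fraction_b must be in [0, 1]")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    s = genotypes.n_sites
    depth = rng.poisson(mean_depth, size=s)
    p = (1 - fraction_b) * genotypes.vaf("A") + fraction_b * genotypes.vaf("B")
    p = p * (1 - error_rate) + (1 - p) * error_rate
    alt = rng.binomial(depth, p)
    bulk = genotypes.sites.copy()
    bulk["ref_count"] = depth - alt
    bulk["alt_count"] = alt
    truth = SyntheticTruth(bulk_fraction_b=fraction_b, genotypes=genotypes)
    return bulk, truth


# ---------------------------------------------------------------------------
# age-graded bulk reference series


@dataclass
class ReferenceSeries:
    """Bulk expression profiles with per-sample age labels.

    ``expr`` is genes x samples (raw counts); ``ages`` gives each sample's
    age. The private program fields allow drawing additional profiles from
    the same gene-module structure (used for staging queries).
    """

    expr: pd.DataFrame
    ages: pd.Series
    _base: np.ndarray | None = field(default=None, repr=False)
    _module_age: np.ndarray | None = field(default=None, repr=False)
    _amplitude: float = 2.0
    _width: float = 0.75
    _unique_ages: list = field(default_factory=list)

    def age_groups(self) -> dict:
        return {s: a for s, a in self.ages.items()}


def _age_profile_mean(base, module_age, age_rank, unique_n, amplitude, width):
    """Expected relative expression at a given age rank (unimodal modules)."""
    mean = base.copy()
    mod = module_age >= 0
    bump = np.exp(-0.5 * ((module_age[mod] - age_rank) / width) ** 2)
    mean[mod] *= 1.0 + amplitude * bump
    return mean


def simulate_reference_series(ages: list, n_genes: int = 2000,
                              n_age_modules: int | None = None, seed: int = 0,
                              n_module_genes: int = 50, amplitude: float = 2.0,
                              library_size: float = 1e6,
                              dispersion: float = 0.05) -> ReferenceSeries:
    """Simulate an age-graded bulk reference expression series.

    Unique ages are ranked; each of ``n_age_modules`` ages (default: all)
    receives a module of genes whose mean expression peaks at that age and
    decays smoothly with age distance (a unimodal trajectory), on top of
    lognormal baseline abundances and negative-binomial counting noise.
    """
    uniq = sorted(set(ages))
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct ages")
    if n_age_modules is None:
        n_age_modules = len(uniq)
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(0.0, 1.0, size=n_genes))
    module_age = np.full(n_genes, -1.0)
    if n_age_modules > 0:
        mod_ages = np.linspace(0, len(uniq) - 1, n_age_modules)
        perm = rng.permutation(n_genes)
        for k, ar in enumerate(mod_ages):
            sel = perm[k * n_module_genes:(k + 1) * n_module_genes]
            module_age[sel] = ar

    series = ReferenceSeries(
        expr=pd.DataFrame(), ages=pd.Series(dtype=object), _base=base,
        _module_age=module_age, _amplitude=amplitude,
        _unique_ages=uniq,
    )
    cols, data = [], []
    for j, a in enumerate(ages):
        prof = sample_profile(series, a, rng, library_size=library_size,
                              dispersion=dispersion)
        cols.append(f"ref{j:03d}")
        data.append(prof)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    series.expr = pd.DataFrame(np.array(data).T, index=genes, columns=cols)
    series.ages = pd.Series(list(ages), index=cols)
    return series


def sample_profile(series: ReferenceSeries, age, rng=None,
                   library_size: float = 1e6,
                   dispersion: float = 0.05) -> np.ndarray:
    """Draw a fresh bulk count profile at ``age`` from a series' program."""
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if age not in series._unique_ages:
        raise ValueError(f"age {age!r} not in the series' age grid")
    rank = series._unique_ages.index(age)
    mean = _age_profile_mean(series._base, series._module_age, rank,
                             len(series._unique_ages), series._amplitude,
                             series._width)
    mean = mean / mean.sum() * library_size
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean / shape)
    else:
        lam = mean
    return rng.poisson(lam).astype(np.int64)
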