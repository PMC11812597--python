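"""Synthetic gene annotations and association summary statistics with ground truth.

Generates the full input universe of the analysis pipeline — gene
annotation tables, per-trait loss-of-function burden summary statistics,
per-trait GWAS variant statistics with clumped hit lists, and LD-block
partitions — from the generative model the analysis assumes:

* per-gene multi-trait effects follow a correlated log-normal, so genes
  vary in both total importance and trait specificity;
* the selection coefficient is the summed squared effect across traits
  (the stabilizing-selection coupling), clipped to the modelled range;
* the aggregate LoF frequency sits at mutation-selection balance,
  ``p_lof = c * mu * L / s_het``, capped at the burden mask's 1% bound;
* burden effect estimates are Normal about the truth with the
  standardized-phenotype standard error ``1 / sqrt(2 n q (1 - q))``;
* GWAS variants near each gene inherit the gene's specificity pattern
  with a drawn regulatory strength, take their frequency from the
  stabilizing-selection equilibrium conditioned on segregating, and are
  observed with the standard GWAS sampling noise.

Every operation is deterministic given its seed, and the returned ground
truth makes each pipeline stage testable without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen import SelectionGrid, nearest_index
from .theory import pvalue_from_z_sq

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SimulatedGwas",
    "generate_genes",
    "generate_burden_stats",
    "generate_gwas_stats",
    "generate_ld_blocks",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic-data generator.

    Defaults emulate the scale of the real studies the pipeline targets:
    18,524 protein-coding genes, 27 genetically uncorrelated traits, a
    burden study of 360,000 individuals, and a genome of 22 chromosomes.
    The gene-effect spread (``f_gene``, ``p_gene``, ``gene_effect_scale``)
    is set so that roughly 0.3% of genes per trait reach burden
    genome-wide significance and the implied selection coefficients span
    the modelled range, mirroring published burden results.  ``gwas_n_eff``
    is an arbitrary power scale (sample size times signal-to-noise), in
    the same units as the pleiotropy simulator.
    """

    n_genes: int = 18_524
    n_traits: int = 27
    n_chromosomes: int = 22
    chrom_length: int = 130_000_000
    burden_n_samples: int = 360_000
    gwas_n_eff: float = 1e7
    # gene-level correlated log-normal effects
    f_gene: float = 0.8
    p_gene: float = 0.5
    gene_effect_scale: float = 4e-5
    # mutational target and balance frequency
    mu_per_site: float = 1.25e-8
    lof_sites_log_median: float = float(np.log(1600.0))
    lof_sites_log_sd: float = 0.7
    lof_freq_scale_c: float = 1.0
    plof_max: float = 0.01
    shet_clip_lo: float = 1e-7
    shet_clip_hi: float = 0.05
    gene_span_log_median: float = float(np.log(30_000.0))
    gene_span_log_sd: float = 0.5
    # GWAS variant layer
    n_variants_per_gene: int = 20
    variant_window: int = 100_000
    variant_strength_median: float = 1e-5
    variant_strength_log_sd: float = 1.5
    gwas_threshold: float = 5e-8
    hit_spacing: int = 100_000
    shet_lookup_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_traits, self.n_chromosomes,
               self.burden_n_samples, self.n_variants_per_gene) < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.p_gene <= 1.0):
            raise ValueError("p_gene must be in [0, 1]")
        if not (0 < self.plof_max <= 0.5):
            raise ValueError("plof_max must be in (0, 0.5]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class GroundTruth:
    """Per-gene generative truth: effects, selection, mutational target."""

    genes: pd.DataFrame = field(repr=False)  # gene, chrom, start, end, midpoint, mu_l, s_het, p_lof
    gamma: np.ndarray = field(repr=False)    # signed per-trait effects, genes x traits

    @property
    def gamma_sq(self) -> np.ndarray:
        return self.gamma**2

    @property
    def specificity(self) -> np.ndarray:
        g2 = self.gamma_sq
        return g2 / g2.sum(axis=1, keepdims=True)


def _gene_positions(config: SyntheticConfig, rng: np.random.Generator):
    """Place gene spans without overlap across chromosomes."""
    chroms, starts, ends = [], [], []
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    for c in range(config.n_chromosomes):
        n = int(per_chrom[c])
        spans = np.round(
            np.exp(rng.normal(config.gene_span_log_median, config.gene_span_log_sd, n))
        ).astype(np.int64)
        free = config.chrom_length - spans.sum() - (n + 1)
        if free <= 0:
            raise ValueError(
                "genes cannot be placed without overlap at the requested density"
            )
        gaps = np.floor(rng.dirichlet(np.ones(n + 1)) * free).astype(np.int64) + 1
        pos = 1
        for i in range(n):
            pos += gaps[i]
            chroms.append(f"chr{c + 1}")
            starts.append(pos)
            ends.append(pos + spans[i] - 1)
            pos += spans[i]
    return chroms, np.asarray(starts), np.asarray(ends)


def generate_genes(config: SyntheticConfig, seed: int | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the gene annotation table and its ground truth.

    Returns ``(genes, truth)`` where ``genes`` is the public annotation
    table (gene, chrom, start, end, midpoint, mu_l, s_het) and ``truth``
    additionally carries the signed per-trait effects and the aggregate
    LoF frequency.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chroms, starts, ends = _gene_positions(config, rng)

    n, k = config.n_genes, config.n_traits
    shared = rng.standard_normal((n, 1))
    indep = rng.standard_normal((n, k))
    normal = np.sqrt(config.p_gene) * indep + np.sqrt(1.0 - config.p_gene) * shared
    gamma_sq = config.gene_effect_scale * np.exp(3.0 * config.f_gene * normal)
    signs = rng.choice([-1.0, 1.0], size=(n, k))
    gamma = signs * np.sqrt(gamma_sq)

    s_het = np.clip(gamma_sq.sum(axis=1), config.shet_clip_lo, config.shet_clip_hi)
    mu_l = config.mu_per_site * np.exp(
        rng.normal(config.lof_sites_log_median, config.lof_sites_log_sd, n)
    )
    p_lof = np.minimum(config.lof_freq_scale_c * mu_l / s_het, config.plof_max)

    genes = pd.DataFrame({
        "gene": [f"G{i:05d}" for i in range(n)],
        "chrom": chroms,
        "start": starts,
        "end": ends,
        "midpoint": (starts + ends) // 2,
        "mu_l": mu_l,
        "s_het": s_het,
    })
    truth_genes = genes.assign(p_lof=p_lof)
    return genes, GroundTruth(genes=truth_genes, gamma=gamma)


def generate_burden_stats(
    truth: GroundTruth, n_samples: int, seed: int
) -> pd.DataFrame:
    """Per-trait LoF burden summary statistics from the generative truth.

    For each gene-trait pair the standard error follows the
    standardized-phenotype convention ``1 / sqrt(2 n q (1 - q))`` with
    ``q`` the aggregate LoF frequency; the estimate is Normal about the
    true effect, and the p-value is the two-sided 1-df chi-square tail.
    Genes with zero LoF frequency carry no information and are skipped
    with a warning.  Returns a long table (trait, gene, beta, se, pval).
    """
    rng = np.random.default_rng(seed)
    q = truth.genes["p_lof"].to_numpy()
    keep = q > 0
    if not np.all(keep):
        warnings.warn(f"{int((~keep).sum())} genes with zero LoF frequency skipped",
                      RuntimeWarning, stacklevel=2)
    se = 1.0 / np.sqrt(2.0 * n_samples * q[keep] * (1.0 - q[keep]))
    gamma = truth.gamma[keep]
    n_genes, n_traits = gamma.shape
    beta = gamma + se[:, None] * rng.standard_normal((n_genes, n_traits))
    pval = pvalue_from_z_sq((beta / se[:, None]) ** 2)
    gene_ids = truth.genes.loc[keep, "gene"].to_numpy()
    return pd.DataFrame({
        "trait": np.repeat(np.arange(n_traits), n_genes),
        "gene": np.tile(gene_ids, n_traits),
        "beta": beta.T.ravel(),
        "se": np.tile(se, n_traits),
        "pval": pval.T.ravel(),
    })


@dataclass
class SimulatedGwas:
    """Variant-level GWAS simulation output with per-trait accessors."""

    variants: pd.DataFrame = field(repr=False)  # variant, chrom, pos, gene, strength, maf, se
    beta: np.ndarray = field(repr=False)        # observed effects, variants x traits
    pval: np.ndarray = field(repr=False)
    gwas_threshold: float = 5e-8
    hit_spacing: int = 100_000

    def trait_table(self, trait: int) -> pd.DataFrame:
        """Full variant summary table for one trait."""
        out = self.variants[["variant", "chrom", "pos", "maf", "se"]].copy()
        out["beta"] = self.beta[:, trait]
        out["pval"] = self.pval[:, trait]
        return out

    def hits(self, trait: int, threshold: float | None = None,
             spacing: int | None = None) -> pd.DataFrame:
        """Clumped genome-wide significant hits for one trait.

        Keeps variants with ``p < threshold``, then greedily prunes them in
        ascending p-value order so that no two retained hits on the same
        chromosome are within ``spacing`` — a stand-in for LD-clump
        independence.
        """
        threshold = self.gwas_threshold if threshold is None else threshold
        spacing = self.hit_spacing if spacing is None else spacing
        tab = self.trait_table(trait)
        tab = tab.loc[tab["pval"] < threshold].sort_values(
            ["pval", "chrom", "pos"], kind="stable")
        kept_pos: dict[str, list[int]] = {}
        kept_rows = []
        for row in tab.itertuples():
            positions = kept_pos.setdefault(row.chrom, [])
            if all(abs(row.pos - p) > spacing for p in positions):
                positions.append(row.pos)
                kept_rows.append(row.Index)
        return tab.loc[kept_rows].reset_index(drop=True)


def generate_gwas_stats(
    truth: GroundTruth,
    config: SyntheticConfig,
    grid: SelectionGrid,
    seed: int,
) -> SimulatedGwas:
    """Simulate variant-level GWAS summary statistics near the genes.

    Each gene receives ``n_variants_per_gene`` variants placed uniformly
    within ``variant_window`` of its span.  A variant's squared-effect
    vector is its gene's specificity pattern scaled by a drawn regulatory
    strength (which is also its selection coefficient); its minor allele
    frequency is sampled from the equilibrium with the nearest grid
    selection coefficient, conditioned on segregating (summary tables
    contain polymorphic sites only); observed statistics add Normal noise
    with variance ``1 / (2 n_eff MAF (1 - MAF))``.
    """
    rng = np.random.default_rng(seed)
    genes = truth.genes
    n_genes = len(genes)
    m = config.n_variants_per_gene
    nv = n_genes * m
    gene_idx = np.repeat(np.arange(n_genes), m)

    lo = np.maximum(genes["start"].to_numpy() - config.variant_window, 1)
    hi = np.minimum(genes["end"].to_numpy() + config.variant_window, config.chrom_length)
    pos = rng.integers(lo[gene_idx], hi[gene_idx] + 1)

    strength = np.exp(rng.normal(
        np.log(config.variant_strength_median), config.variant_strength_log_sd, nv))
    psi = truth.specificity[gene_idx]           # variants inherit gene specificity
    alpha_sq = strength[:, None] * psi

    lookup = np.clip(strength * config.shet_lookup_scale,
                     grid.s_het_values[0], grid.s_het_values[-1])
    idx = np.atleast_1d(nearest_index(grid, lookup))
    n_hap = grid.params.n_haploids
    freq = np.empty(nv)
    for gi in np.unique(idx):
        mask = idx == gi
        mass = grid.distributions[gi].mass[1:].copy()  # condition on segregating
        mass /= mass.sum()
        counts = 1 + rng.choice(mass.size, size=int(mask.sum()), p=mass)
        freq[mask] = counts / n_hap
    maf = np.minimum(freq, 1.0 - freq)

    se = 1.0 / np.sqrt(2.0 * config.gwas_n_eff * maf * (1.0 - maf))
    signs = np.sign(truth.gamma[gene_idx])
    beta = signs * np.sqrt(alpha_sq) + se[:, None] * rng.standard_normal(alpha_sq.shape)
    pval = pvalue_from_z_sq((beta / se[:, None]) ** 2)

    variants = pd.DataFrame({
        "variant": [f"v{i:07d}" for i in range(nv)],
        "chrom": genes["chrom"].to_numpy()[gene_idx],
        "pos": pos,
        "gene": genes["gene"].to_numpy()[gene_idx],
        "strength": strength,
        "maf": maf,
        "se": se,
    })
    return SimulatedGwas(
        variants=variants, beta=beta, pval=pval,
        gwas_threshold=config.gwas_threshold, hit_spacing=config.hit_spacing,
    )


def generate_ld_blocks(
    chrom_lengths: dict[str, int],
    mean_size: int,
    seed: int,
) -> pd.DataFrame:
    """Partition each chromosome into contiguous blocks around a mean size.

    Returns a BED-style table (chrom, start, end; 0-based half-open)
    whose blocks tile ``[0, length)`` exactly.
    """
    if mean_size <= 0:
        raise ValueError("mean_size must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in chrom_lengths.items():
        pos = 0
        while pos < length:
            size = int(mean_size * rng.gamma(4.0, 0.25))
            size = max(size, 1)
            end = min(pos + size, length)
            rows.append({"chrom": chrom, "start": pos, "end": end})
            pos = end
    return pd.DataFrame(rows)
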