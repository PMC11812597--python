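# traitspec

Population-genetic models of **why rare-variant burden tests and common-variant
GWAS prioritize different genes**, as a tested, reusable Python package.

Gene-level loss-of-function (LoF) burden tests and variant-level GWAS are
conceptually similar association designs, yet they rank genes very
differently. `traitspec` implements the stabilizing-selection theory that
explains this, the simulations that illustrate it, and the summary-statistics
pipeline that quantifies it — all exercisable on synthetic data with full
ground truth, no downloads required.

## The model in brief

For a gene with per-trait LoF effects γ_t (trait 1 under study) define

- **trait importance** γ₁² — how much the gene affects the study trait;
- **trait specificity** Ψ_G = γ₁² / Σ_t γ_t² — importance relative to the
  gene's total effect across all fitness-relevant traits (Ψ_V analogously
  for a variant with effects α_t).

Under stabilizing selection the heterozygote selection coefficient is
approximately the summed importance, s_het ≈ Σ_t γ_t². At
mutation–selection balance the aggregate LoF frequency satisfies
p_LoF(1−p_LoF) ∝ μL / s_het (μ per-site mutation rate, L mutational
target size), and the expected burden association strength

    E[z²] ∝ γ₁² · p_LoF(1−p_LoF) ∝ μL · Ψ_G

depends on the gene's *specificity* and *length* — not its importance.
GWAS obey the variant-level analogue (E[z²] ∝ Ψ_V), plus drift: a
variant's realized heritability 2α₁²p(1−p) has E[p(1−p)] = 1/Σ_t α_t², so
among strongly selected variants the p-value ranking is driven by luck in
allele frequency ("flattening").

The package provides:

| module | contents |
| --- | --- |
| `traitspec.popgen` | discrete-time Wright–Fisher equilibrium distributions under heterozygote selection with one-way mutation and no-fixation conditioning; selection-coefficient grids; a forward-simulation oracle |
| `traitspec.theory` | specificity, the unbiased squared-effect estimator γ̂²−s², expected association strength, realized heritability, the z²−1 heritability proxy, Bonferroni thresholds, the flattening curve |
| `traitspec.realized` | the realized-heritability simulation (drift decoupling) |
| `traitspec.pleiotropy` | the 18-trait GWAS-hit simulator (correlated log-normal effects, L1-norm selection, hit quartile summaries) |
| `traitspec.loci` | GWAS locus definition (1 Mb transitive closure), gene assignment, power-matched top-locus selection, LD-block comparison, nearest-gene hit counts |
| `traitspec.binning` | quantile binning, per-bin means ± empirical SE, inverse-variance weighting, enrichment normalization |
| `traitspec.synthetic` | generators for gene annotations, burden and GWAS summary statistics, and LD blocks, with ground truth |
| `traitspec.tables` / CLI | TSV/BED readers and writers with schema validation; `traitspec` command-line entry point |

## Worked example

Solve the equilibrium frequency distribution for a strongly constrained
variant and check the mutation–selection balance limit:

```python
from traitspec.popgen import (PopulationParams, stationary_distribution,
                              distribution_moments)

params = PopulationParams(n_diploids=2000, mut_rate=1e-6)
dist = stationary_distribution(params, s_het=0.01)
mean_p, mean_pq = distribution_moments(dist)
print(f"mean frequency {mean_p:.3g}  E[p(1-p)] {mean_pq:.3g}  mu/s {1e-6/0.01:.3g}")
```

prints

```
mean frequency 0.000104  E[p(1-p)] 0.000103  mu/s 0.0001
```

— the mean frequency sits within 4% of the deterministic balance μ/s_het.
Simulate realized heritability across selection strengths and measure the
drift decoupling:

```python
from traitspec.popgen import build_selection_grid
from traitspec.realized import RealizedSimConfig, run_realized_sim, decoupling_summary

grid = build_selection_grid(PopulationParams(2000, 1.25e-7), lo=1e-6, hi=0.5)
cfg = RealizedSimConfig(shet_lo=1e-6, shet_hi=2.3e-3)   # diffusion-rescaled
rows = run_realized_sim(cfg, grid, seed=1)
print(decoupling_summary(rows, n_diploids=2000))
```

```
{'weak':   {'rho': 0.534, 'n': 35650, 'degenerate': False},
 'strong': {'rho': 0.081, 'n': 3950,  'degenerate': False}}
```

Among effectively neutral variants (2N·s_het < 1) realized heritability
tracks effect size (Spearman ρ ≈ 0.53); among strongly selected ones
(2N·s_het > 5) the ranking is essentially random (ρ ≈ 0.08) — drift, not
importance, decides which large-effect variants a GWAS can see.

The same flow is available from the shell:

```bash
traitspec make-synth --seed 1 --out-dir synth/
traitspec define-loci --hits synth/hits.0.tsv --genes synth/genes.tsv --out synth/loci.tsv
traitspec compare-loci --hits synth/hits.0.tsv --genes synth/genes.tsv \
    --burden synth/burden.0.tsv --out synth/concordance.tsv
traitspec bin-summarize --table synth/truth.tsv --by s_het --value mu_l \
    --n-bins 100 --out synth/bins.tsv
```

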