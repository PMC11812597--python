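# Methods

## Model

Traits are assumed to be under stabilizing selection. For a variant with
per-trait effects α_t (standardized-trait units; trait 1 is the trait under
study) the strength of selection against carriers is, to leading order,
proportional to the summed squared effects, and we work in units where the
heterozygote selection coefficient is exactly

    s_het = Σ_t α_t²            (variants)    s_het ≈ Σ_t γ_t²   (gene LoFs).

Any proportionality constant between "summed squared effect" and fitness can
be absorbed into the arbitrary power scale of the association model (see
below), so results are interpreted up to study-wide constants; every
"proportional to" relation in `traitspec.theory` therefore carries an
explicit scale argument defaulting to one.

### Equilibrium allele-frequency distributions

`traitspec.popgen` models a single biallelic site in a panmictic population
of N diploids by a discrete-time Wright–Fisher chain on derived-allele
counts 0..2N with per-generation update

1. **viability selection** with Hardy–Weinberg genotype frequencies and
   fitnesses (1, 1−s_het, 1) for ancestral homozygote / heterozygote /
   derived homozygote — selection against heterozygous carriers only, the
   standard first-order reduction of stabilizing selection on a rare
   variant. A `genic=True` switch instead assigns the derived homozygote
   fitness 1−2s_het; for the rare frequencies that dominate here the two are
   nearly indistinguishable (a unit test checks the qualitative difference
   at common frequencies).
2. **one-way mutation** ancestral → derived at rate μ per copy per
   generation (the ancestral allele is treated as known; back mutation is
   ignored).
3. **binomial resampling** of 2N copies.

Because mutation is one-way, the fixed class (count 2N) is absorbing and
the only non-degenerate equilibrium is conditional on non-fixation: the
fixed class is excluded and the remaining mass renormalized at each solve
step. The fixed point of that iteration is the quasi-stationary
distribution — the leading left eigenvector of the transition matrix
restricted to counts 0..2N−1. We compute it by a shift-inverted sparse
eigensolve (ARPACK, shift 1+10⁻⁶, deterministic start vector, tolerance
10⁻¹³) with a renormalized power iteration (residual 10⁻¹⁰, at most 10⁶
steps) as fallback, and verify the residual ‖vP − λv‖₁ ≤ 10⁻⁸.

The choice of the quasi-stationary law over the per-row "rejection"
conditioning matters: with heterozygote-only fitnesses, frequencies above
one half are pushed *toward* fixation, and per-row renormalization piles
spurious mass just below the fixed class (at N=2,000, s_het=0.01 it
inflates the mean frequency 250-fold). The quasi-stationary law suppresses
that region through its imminent absorption hazard and reproduces the
mutation–selection balance limit E[p] ≈ μ/s_het to a few percent.

Binomial rows are evaluated on a ±(10 sd + 30) window, entries below 10⁻¹²
zeroed, and each row renormalized; a unit test confirms the truncation is
inconsequential (agreement with the dense binomial to 10⁻¹⁰).

**Forward-simulation oracle.** `forward_simulate` runs the identical
update by direct sampling, and on drawing a fixation restarts the
trajectory from a state sampled uniformly from its own past — a
single-particle occupation-measure resampling scheme whose empirical law
converges to the quasi-stationary distribution. It shares only the
one-generation update formula with the solver (no transition matrix, no
truncation, no linear algebra), making it a genuinely independent check;
at N=50, μ=10⁻³ the total-variation distance after 10⁶ generations is
≈ 0.005.

**Scale.** The production configuration is N=20,000 diploids,
μ=1.25×10⁻⁸, and a 50-point log-uniform grid of s_het from 10⁻⁷ to 0.05.
All tests and the acceptance script run a diffusion-rescaled population of
N=2,000 with 2Nμ and 2N·s_het preserved (μ=1.25×10⁻⁷, grid 10⁻⁶–0.5, all
selection coefficients multiplied by 10 before grid lookup). The rescaled
grid solves in about 75 s on one CPU; the production grid is available by
configuration.

### Association model

An observed effect is Normal about the truth with sampling variance
1/(2·N_eff·MAF(1−MAF)); the squared z-score 2·N_eff·MAF(1−MAF)·α̂² is 1-df
chi-square under the null, and p-values are two-sided via the chi-square
upper tail. N_eff folds together sample size and signal-to-noise and is
deliberately an arbitrary scale. The unbiased estimator of a squared
effect is α̂² − se² (variance 4α²se² + 2se⁴); it may be negative, and
unbiasedness — not positivity — is its contract.

## Simulations

### Realized heritability

1,000 selection coefficients log-uniformly spaced (as a deterministic
grid) over 10⁻⁷–2.3×10⁻⁴ production scale, 50 variants each; population
frequencies drawn from the equilibrium with the nearest grid coefficient
**conditioned on segregation** (the simulated objects are variants —
polymorphic by definition; without the conditioning ~99% of draws are
monomorphic at these mutation rates and every summary is dominated by
zero-heritability ties); GWAS-sample frequencies resampled as
Binomial(600,000, f); realized heritability 2·s_het·f̃(1−f̃) under the
constant-specificity convention (effect magnitude √s_het), normalized to
the simulated maximum. Decoupling strata are defined on 2N·s_het with
weak < 1 and strong > 5; the configured selection range tops out at
2N·s_het ≈ 9.2, so a strong cut of 10 would leave an empty stratum — 5 is
the largest round threshold with a usable drift-dominated stratum.

### Pleiotropy of GWAS hits

Squared-effect vectors over 18 traits are drawn per position as
`scale · exp(3f · MVN(0, pI + (1−p)11ᵀ))` element-wise, with f=0.33,
p=0.5; the selection strength is the L1 norm of the squared effects;
frequencies come from the nearest-grid equilibrium; association adds the
standard sampling noise centred on the (unsquared) effect with
N_eff=10⁷, and hits are cells with p < 10⁻⁵. Two conventions for the
scale constant are implemented: `10^(−7f)` (default) and `1e−7·f`. Under
the latter, effects sit three orders of magnitude below the sampling-noise
floor at the default N_eff, all "hits" are pure null draws, and no
quartile structure exists; the default convention produces genuine
genome-wide-significant signal and reproduces the three published quartile
directions (top-quartile hits are at higher relative MAF, are more
trait-specific, and are hits for more traits). Default runs here use 10⁵
positions (production 10⁷; the matrix is generated in blocks either way);
robustness is checked by one-at-a-time 4-point sweeps of N_eff, the hit
threshold, p, and f at comparable relative widths around the defaults.
Strongly shared regimes (p ≤ 0.2, cross-trait correlation ≥ 0.8) invert
the MAF-quartile direction — a genuinely different model, outside the
swept neighbourhood.

## Locus pipeline

Coordinates are 1-based inclusive internally; BED input (0-based
half-open) is converted on read. Locus grouping processes LD-clumped hits
in ascending p-value order (ties by chromosome, then position), seeds a
locus with the most significant unassigned hit, and transitively absorbs
every unassigned hit within 1 Mb of any member; because closure removes
everything within the window of a finished locus, the closure equals the
maximal run of unassigned hits with consecutive gaps ≤ 1 Mb, which the
implementation exploits. Power-matched selection ranks loci by minimum
GWAS p and walks down, taking each locus's burden-significant genes (or
its single smallest-burden-p gene if none, or nothing if the locus spans
no genes — empty loci still consume rank slots, which keeps the overlap
estimate conservative) until the selected-gene count reaches the
genome-wide burden-significant count; the final locus contributes in full
(a `strict_stop` switch truncates instead). In the LD-block comparison,
any run of genomically consecutive informative blocks sharing the same
minimum-burden gene is dropped entirely — the conservative reading of the
duplicate rule. Nearest-gene assignment uses gene midpoints with
equidistant ties to the smaller start coordinate.

## Synthetic data

The generator emulates the schemas and the statistical structure of the
real inputs (variant-level GWAS tables, gene-level burden tables,
constraint-style gene annotations, LD-block BEDs) with full ground truth:

- **Genes** (18,524 over 22 chromosomes of 130 Mb): non-overlapping spans
  (log-normal, median 30 kb); per-trait effects over 27 traits from the
  correlated log-normal with f_gene=0.8, p_gene=0.5 and scale 4×10⁻⁵,
  chosen once so that the implied s_het = Σγ_t² (clipped to the modelled
  range 10⁻⁷–0.05) has a realistic spread (median ≈ 4×10⁻³) and roughly
  0.3% of genes per trait reach burden genome-wide significance
  (p < 2.7×10⁻⁶), the order observed in published biobank burden scans.
- **Mutational target** μL = μ·L with L log-normal (median 1,600 sites,
  log-sd 0.7, a coding-length proxy); aggregate LoF frequency
  p_LoF = μL/s_het capped at 1% (the burden mask's frequency bound).
- **Burden statistics**: se = 1/√(2n·q(1−q)) with n=360,000
  (standardized-phenotype convention), estimates Normal about the true
  γ_t.
- **GWAS variants**: 20 per gene within ±100 kb; each inherits its gene's
  specificity pattern with a drawn total strength (log-normal, median
  10⁻⁵, log-sd 1.5) that is also its selection coefficient; frequencies
  from the nearest-grid equilibrium conditioned on segregation; noise at
  N_eff=10⁷ (the simulator's power scale — at face-value biobank sample
  sizes and exact s_het=Σα² units, equilibrium theory permits essentially
  no genome-wide-significant hits, which is the flattening result itself;
  the arbitrary scale restores the empirically observed hit density).
  Hit lists keep p < 5×10⁻⁸ with a 100 kb greedy spacing standing in for
  clump independence.

What the generator does **not** emulate: LD between variants, realistic
gene-length and recombination maps, ascertainment of genotyping arrays,
population structure, or non-equilibrium demography. Passing tests
therefore demonstrate the internal consistency of the theory, estimators,
and pipeline under the model's own assumptions — not calibration against
real biobank data.

## Numerical conventions and degenerate inputs

- Quantile bins are equal-count by stable rank; remainders go one-per-bin
  to the lowest bins; single-item bins report se 0 with a degeneracy flag.
- Inverse-variance weights are 1/se²; combined se = √(1/Σw). Enrichment
  renormalization divides by the mean by default ("average to one"); a
  sum-to-one mode is provided since both conventions appear in practice.
- Traits whose genome-wide mean z²−1 is non-positive are excluded from
  enrichment combination with a warning.
- Monomorphic positions have undefined sampling variance and are excluded
  from association with a warning; traits with fewer than four hits are
  flagged and excluded from quartile summaries; strata or concordance sets
  too small for a rank correlation return a flagged `None` rather than an
  error.
- Log-scale grid lookups clamp out-of-range values to the nearest
  endpoint; exact log-midpoint ties resolve to the lower index.
- All randomness flows through `numpy.random.Generator` seeded per
  operation; multi-stage runs derive child seeds via `SeedSequence`.

## Known limitations

- The quasi-stationary equilibrium treats the population as at
  equilibrium; bottlenecks and expansions (which shape real rare-variant
  frequency spectra) are out of scope.
- The flattening curve and all "expected z²" statements are up to
  study-wide constants; no attempt is made to fit those constants.
- The pleiotropy simulator's four parameters are stylized; only the
  qualitative quartile orderings, not their magnitudes, are claimed.
- Burden aggregation is modelled at the gene level directly; individual
  LoF variants within a gene are not simulated.
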