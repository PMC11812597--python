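"""Multi-trait GWAS-hit simulator: drift, specificity, and apparent pleiotropy.

Each simulated position carries a vector of squared effects across traits
drawn from a correlated log-normal: a shared component (weight ``1 - p``)
makes some positions broadly impactful while an independent component
(weight ``p``) spreads specificity.  The strength of selection against a
position is the L1 norm of its squared effects, its minor allele frequency
is drawn from the matching stabilizing-selection equilibrium, and observed
per-trait association statistics add Normal noise with the standard
GWAS sampling variance ``1 / (2 N_eff MAF (1 - MAF))``.  Genome-wide
significant hits are then binned into p-value quartiles to summarize how
MAF, trait specificity, and cross-trait hit counts vary with significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .popgen import SelectionGrid, nearest_index
from .theory import pvalue_from_z_sq

__all__ = [
    "PleiotropySimConfig",
    "draw_effect_matrix",
    "variant_specificities",
    "assign_frequencies",
    "simulate_association",
    "call_and_bin_hits",
    "run_pleiotropy_sim",
]


@dataclass(frozen=True)
class PleiotropySimConfig:
    """Parameters of the pleiotropy simulation.

    ``sim_f`` controls the spread of total effect sizes and ``sim_p`` the
    balance between trait-independent and shared effect components;
    ``n_eff`` is an arbitrary scale folding together sample size and
    environmental noise.  Production defaults: 18 traits, 1e7 positions
    (not necessarily segregating), ``sim_f=0.33``, ``sim_p=0.5``,
    ``n_eff=1e7``, hit threshold 1e-5.

    ``prefactor`` selects the effect-scale constant: ``"exponent"`` (the
    default) uses ``10 ** (-7 * sim_f)``, which produces genuine
    genome-wide-significant signal at the default power scale, while
    ``"scaled"`` uses ``1e-7 * sim_f``, under which effects are far below
    the sampling noise floor and hits are essentially pure null draws.
    ``noise_mean`` selects whether observed effects are centred on the
    effect (``"effect"``, the standard GWAS estimator convention) or on
    the squared effect (``"squared"``).
    ``shet_lookup_scale`` rescales selection strengths before the
    frequency-grid lookup, for use with diffusion-rescaled (smaller ``N``)
    grids.
    """

    n_traits: int = 18
    n_positions: int = 10_000_000
    sim_f: float = 0.33
    sim_p: float = 0.5
    n_eff: float = 10_000_000.0
    hit_threshold: float = 1e-5
    prefactor: str = "exponent"
    noise_mean: str = "effect"
    shet_lookup_scale: float = 1.0
    block_size: int = 500_000

    def __post_init__(self) -> None:
        if self.n_traits < 2:
            raise ValueError("n_traits must be >= 2")
        if not (0.0 <= self.sim_p <= 1.0):
            raise ValueError("sim_p must be in [0, 1]")
        if not (0.0 < self.hit_threshold < 1.0):
            raise ValueError("hit_threshold must be in (0, 1)")
        if self.prefactor not in ("scaled", "exponent"):
            raise ValueError("prefactor must be 'scaled' or 'exponent'")
        if self.noise_mean not in ("effect", "squared"):
            raise ValueError("noise_mean must be 'effect' or 'squared'")
        if self.n_positions < 1 or self.n_eff <= 0 or self.sim_f <= 0:
            raise ValueError("n_positions, n_eff and sim_f must be positive")

    @property
    def scale_constant(self) -> float:
        if self.prefactor == "scaled":
            return 1e-7 * self.sim_f
        return 10.0 ** (-7.0 * self.sim_f)


def draw_effect_matrix(
    config: PleiotropySimConfig,
    seed: int | np.random.Generator,
    n_positions: int | None = None,
) -> np.ndarray:
    """Draw the (positions x traits) matrix of squared effects.

    Per position the log squared effects are ``3 sim_f`` times a
    multivariate Normal with covariance ``sim_p I + (1 - sim_p) 11^T``
    (unit variances, pairwise correlation ``1 - sim_p``), exponentiated
    element-wise and multiplied by the configured scale constant.
    """
    rng = np.random.default_rng(seed)
    n = config.n_positions if n_positions is None else n_positions
    k = config.n_traits
    shared = rng.standard_normal((n, 1))
    indep = rng.standard_normal((n, k))
    normal = np.sqrt(config.sim_p) * indep + np.sqrt(1.0 - config.sim_p) * shared
    return config.scale_constant * np.exp(3.0 * config.sim_f * normal)


def variant_specificities(effects_sq: np.ndarray) -> np.ndarray:
    """Per-trait specificity ``Psi_V`` matrix: each squared effect over its row sum."""
    totals = effects_sq.sum(axis=1, keepdims=True)
    return effects_sq / totals


def assign_frequencies(
    selection_strengths: np.ndarray,
    grid: SelectionGrid,
    seed: int | np.random.Generator,
    lookup_scale: float = 1.0,
) -> np.ndarray:
    """Minor allele frequency per position from the matching equilibrium.

    Each position's frequency is sampled from the grid distribution whose
    selection coefficient is nearest (in log space, after ``lookup_scale``)
    to the position's selection strength, then folded to the minor-allele
    convention ``min(f, 1 - f)``.
    """
    rng = np.random.default_rng(seed)
    strengths = np.asarray(selection_strengths, dtype=float) * lookup_scale
    idx = np.atleast_1d(nearest_index(grid, strengths))
    n_hap = grid.params.n_haploids
    freqs = np.empty(strengths.shape)
    for gi in np.unique(idx):
        mask = idx == gi
        dist = grid.distributions[gi]
        counts = rng.choice(len(dist.mass), size=int(mask.sum()), p=dist.mass)
        freqs[mask] = counts / n_hap
    return np.minimum(freqs, 1.0 - freqs)


def simulate_association(
    effects_sq: np.ndarray,
    mafs: np.ndarray,
    n_eff: float,
    seed: int | np.random.Generator,
    noise_mean: str = "effect",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed effects, squared z-scores, and p-values per position-trait cell.

    The observed effect is Normal about the true mean with sampling variance
    ``1 / (2 n_eff MAF (1 - MAF))``; the squared z-score is
    ``2 n_eff MAF (1 - MAF)`` times the squared observed effect, 1-df
    chi-square under the null.  Monomorphic positions (MAF 0) have undefined
    sampling variance and are excluded (NaN rows) with a warning.
    """
    effects_sq = np.atleast_2d(np.asarray(effects_sq, dtype=float))
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs < 0) | (mafs > 0.5)):
        raise ValueError("MAFs must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    segregating = mafs > 0
    if not np.all(segregating):
        warnings.warn(
            f"{int((~segregating).sum())} monomorphic positions excluded from "
            "association (undefined sampling variance)",
            RuntimeWarning, stacklevel=2,
        )
    info = np.where(segregating, 2.0 * n_eff * mafs * (1.0 - mafs), np.nan)
    se = 1.0 / np.sqrt(info)
    true_mean = effects_sq if noise_mean == "squared" else np.sqrt(effects_sq)
    observed = true_mean + se[:, None] * rng.standard_normal(effects_sq.shape)
    z_sq = info[:, None] * observed**2
    p = np.where(np.isfinite(z_sq), pvalue_from_z_sq(np.nan_to_num(z_sq)), np.nan)
    return observed, z_sq, p


def call_and_bin_hits(
    p_values: np.ndarray,
    mafs: np.ndarray,
    specificities: np.ndarray,
    hit_threshold: float,
) -> pd.DataFrame:
    """Quartile summaries of genome-wide significant hits, per trait.

    Per trait, hits are position-trait cells with ``p < hit_threshold``;
    they are split into four p-value quartiles (quartile 1 the most
    significant; ties broken by stable position order).  Each quartile
    reports the mean MAF relative to the trait's all-hits mean MAF, the
    mean focal-trait specificity, and the mean number of traits in which
    the hit position is genome-wide significant.  Traits with fewer than
    four hits are flagged ``excluded`` and carry no quartile rows.
    """
    p_values = np.atleast_2d(p_values)
    specificities = np.atleast_2d(specificities)
    n_pos, n_traits = p_values.shape
    with np.errstate(invalid="ignore"):
        hit_flags = p_values < hit_threshold  # NaN compares False
    traits_hit_per_pos = hit_flags.sum(axis=1)

    records = []
    for t in range(n_traits):
        hit_idx = np.flatnonzero(hit_flags[:, t])
        n_hits = hit_idx.size
        if n_hits < 4:
            records.append({
                "trait": t, "quartile": np.nan, "n_hits": n_hits,
                "mean_rel_maf": np.nan, "mean_psi": np.nan,
                "mean_traits_hit": np.nan, "excluded": True,
            })
            continue
        order = hit_idx[np.argsort(p_values[hit_idx, t], kind="stable")]
        all_mean_maf = mafs[hit_idx].mean()
        for q, chunk in enumerate(np.array_split(order, 4), start=1):
            records.append({
                "trait": t, "quartile": q, "n_hits": int(chunk.size),
                "mean_rel_maf": float(mafs[chunk].mean() / all_mean_maf),
                "mean_psi": float(specificities[chunk, t].mean()),
                "mean_traits_hit": float(traits_hit_per_pos[chunk].mean()),
                "excluded": False,
            })
    return pd.DataFrame.from_records(records)


def aggregate_quartiles(summary: pd.DataFrame) -> pd.DataFrame:
    """Across-trait average of the per-trait quartile summaries.

    Simple mean over the traits that were not excluded; one row per
    quartile with the total hit count.
    """
    kept = summary.loc[~summary["excluded"]]
    if kept.empty:
        return pd.DataFrame(
            columns=["quartile", "n_hits", "mean_rel_maf", "mean_psi", "mean_traits_hit"]
        )
    return (
        kept.groupby("quartile")
        .agg(n_hits=("n_hits", "sum"), mean_rel_maf=("mean_rel_maf", "mean"),
             mean_psi=("mean_psi", "mean"), mean_traits_hit=("mean_traits_hit", "mean"))
        .reset_index()
    )


def run_pleiotropy_sim(
    config: PleiotropySimConfig,
    grid: SelectionGrid,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end pleiotropy simulation.

    Positions are processed in blocks so the full effect matrix for the
    production-scale run is never materialized.  Returns the per-trait
    quartile summary and a per-hit table
    (position, trait, p_value, maf, psi, n_traits_hit).
    """
    ss = np.random.SeedSequence(seed)
    n_blocks = int(np.ceil(config.n_positions / config.block_size))
    block_seeds = ss.spawn(n_blocks)

    hit_pos, hit_trait, hit_p = [], [], []
    hit_maf, hit_psi, hit_ntraits = [], [], []
    # per-trait running totals over *all* hits, for the relative-MAF baseline
    maf_sum = np.zeros(config.n_traits)
    hit_count = np.zeros(config.n_traits, dtype=np.int64)

    offset = 0
    for bs in block_seeds:
        n_block = min(config.block_size, config.n_positions - offset)
        child = np.random.default_rng(bs)
        effects = draw_effect_matrix(config, child, n_positions=n_block)
        strengths = effects.sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mafs = assign_frequencies(strengths, grid, child,
                                      lookup_scale=config.shet_lookup_scale)
            _, _, p = simulate_association(effects, mafs, config.n_eff, child,
                                           noise_mean=config.noise_mean)
        psi = variant_specificities(effects)
        with np.errstate(invalid="ignore"):
            flags = p < config.hit_threshold
        traits_hit = flags.sum(axis=1)
        pos_idx, trait_idx = np.nonzero(flags)
        hit_pos.append(pos_idx + offset)
        hit_trait.append(trait_idx)
        hit_p.append(p[pos_idx, trait_idx])
        hit_maf.append(mafs[pos_idx])
        hit_psi.append(psi[pos_idx, trait_idx])
        hit_ntraits.append(traits_hit[pos_idx])
        np.add.at(maf_sum, trait_idx, mafs[pos_idx])
        np.add.at(hit_count, trait_idx, 1)
        offset += n_block

    hits = pd.DataFrame({
        "position": np.concatenate(hit_pos) if hit_pos else np.array([], dtype=int),
        "trait": np.concatenate(hit_trait) if hit_trait else np.array([], dtype=int),
        "p_value": np.concatenate(hit_p) if hit_p else np.array([]),
        "maf": np.concatenate(hit_maf) if hit_maf else np.array([]),
        "psi": np.concatenate(hit_psi) if hit_psi else np.array([]),
        "n_traits_hit": np.concatenate(hit_ntraits) if hit_ntraits else np.array([], dtype=int),
    })

    records = []
    for t in range(config.n_traits):
        sub = hits.loc[hits["trait"] == t]
        n_hits = len(sub)
        if n_hits < 4:
            records.append({
                "trait": t, "quartile": np.nan, "n_hits": n_hits,
                "mean_rel_maf": np.nan, "mean_psi": np.nan,
                "mean_traits_hit": np.nan, "excluded": True,
            })
            continue
        sub = sub.sort_values(["p_value", "position"], kind="stable")
        baseline = maf_sum[t] / hit_count[t]
        for q, chunk in enumerate(np.array_split(np.arange(n_hits), 4), start=1):
            part = sub.iloc[chunk]
            records.append({
                "trait": t, "quartile": q, "n_hits": int(len(part)),
                "mean_rel_maf": float(part["maf"].mean() / baseline),
                "mean_psi": float(part["psi"].mean()),
                "mean_traits_hit": float(part["n_traits_hit"].mean()),
                "excluded": False,
            })
    summary = pd.DataFrame.from_records(records)
    return summary, hits


def config_sweep(config: PleiotropySimConfig, param: str, values) -> list[PleiotropySimConfig]:
    """One-at-a-time parameter sweep helper (robustness checks)."""
    return [replace(config, **{param: v}) for v in values]
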