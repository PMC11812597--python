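"""Quantile binning, per-bin summaries, and cross-trait enrichment combination.

The machinery for summary-statistic trend analyses: genes are binned into
equal-count quantiles of a variable (selection coefficient, mutational
target size, ...), per-bin means carry empirical standard errors
(sd / sqrt(n)), per-trait relative heritability proxies (``z^2 - 1`` over
its genome-wide mean) are combined across traits by inverse-variance
weighting, and combined enrichments are renormalized to average (or sum)
to one.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "quantile_bins",
    "bin_mean_se",
    "ivw_combine",
    "enrichment_normalize",
    "relative_proxy_enrichment",
]


def quantile_bins(values, n_bins: int) -> np.ndarray:
    """Equal-count bin assignment by rank.

    Bin sizes differ by at most one; when the count does not divide evenly
    the remainder is distributed one item per lowest bins.  Ties are kept
    adjacent by a stable sort on (value, input order).  Returns an integer
    bin index (0-based, ascending in the binned variable) per input item.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n = values.size
    if n < n_bins:
        raise ValueError(f"cannot split {n} values into {n_bins} bins")
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    order = np.argsort(values, kind="stable")
    assignments = np.empty(n, dtype=int)
    assignments[order] = np.repeat(np.arange(n_bins), sizes)
    return assignments


def bin_mean_se(values, assignments) -> pd.DataFrame:
    """Per-bin arithmetic mean with empirical standard error (sd / sqrt(n)).

    Single-item bins report a standard error of zero with a degeneracy
    flag rather than failing.  Returns one row per bin with columns
    ``bin, mean, se, n, lo, hi, degenerate``.
    """
    values = np.asarray(values, dtype=float)
    assignments = np.asarray(assignments)
    rows = []
    for b in np.unique(assignments):
        v = values[assignments == b]
        degenerate = v.size < 2
        se = 0.0 if degenerate else float(v.std(ddof=1) / np.sqrt(v.size))
        rows.append({
            "bin": int(b), "mean": float(v.mean()), "se": se, "n": int(v.size),
            "lo": float(v.min()), "hi": float(v.max()), "degenerate": degenerate,
        })
    return pd.DataFrame(rows).sort_values("bin").reset_index(drop=True)


def ivw_combine(estimates, standard_errors) -> tuple[float, float]:
    """Inverse-variance weighted combination of independent estimates.

    Weights are ``1 / se^2``; the combined standard error is the square
    root of the reciprocal of the total weight — the minimum-variance
    unbiased combination under independence.
    """
    estimates = np.asarray(estimates, dtype=float)
    se = np.asarray(standard_errors, dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    return float(np.sum(w * estimates) / np.sum(w)), float(np.sqrt(1.0 / np.sum(w)))


def enrichment_normalize(values, mode: str = "mean") -> np.ndarray:
    """Rescale enrichment values to average to one (or sum to one).

    ``mode="mean"`` divides by the mean (the burden-analysis convention);
    ``mode="sum"`` divides by the sum.
    """
    values = np.asarray(values, dtype=float)
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    denom = values.mean() if mode == "mean" else values.sum()
    if denom == 0 or not np.isfinite(denom):
        raise ValueError("cannot normalize values with zero mean/sum")
    return values / denom


def relative_proxy_enrichment(
    z_sq: pd.DataFrame,
    assignments,
    normalize: str = "mean",
) -> pd.DataFrame:
    """Per-bin cross-trait heritability enrichment from squared z-scores.

    Per trait, the heritability proxy ``z^2 - 1`` is averaged within each
    bin relative to its genome-wide average, with an empirical standard
    error from the within-bin standard deviation of the relative values;
    the per-trait enrichments are then combined across traits by inverse-
    variance weighting and the combined values renormalized to average
    (``normalize="mean"``) or sum (``"sum"``) to one.

    Parameters
    ----------
    z_sq : DataFrame, genes x traits
        Squared z-scores, aligned on genes across traits.
    assignments : array-like
        Bin index per gene, from :func:`quantile_bins`.

    Traits whose genome-wide mean proxy is not positive carry no
    heritability signal to normalize against and are excluded with a
    warning.
    """
    assignments = np.asarray(assignments)
    if len(z_sq) != assignments.size:
        raise ValueError("assignments must align with the gene axis of z_sq")
    bins = np.unique(assignments)
    per_trait_mean = {}
    per_trait_se = {}
    for trait in z_sq.columns:
        proxy = z_sq[trait].to_numpy() - 1.0
        global_mean = proxy.mean()
        if global_mean <= 0:
            warnings.warn(
                f"trait {trait!r} has non-positive mean heritability proxy; excluded",
                RuntimeWarning, stacklevel=2,
            )
            continue
        rel = proxy / global_mean
        summary = bin_mean_se(rel, assignments)
        # degenerate (zero) standard errors cannot be inverse-variance
        # weighted; floor them at a tiny positive value
        se = np.where(summary["se"] > 0, summary["se"], 1e-12)
        per_trait_mean[trait] = summary["mean"].to_numpy()
        per_trait_se[trait] = se
    if not per_trait_mean:
        raise ValueError("no trait with positive mean heritability proxy")
    combined = np.empty(bins.size)
    combined_se = np.empty(bins.size)
    traits = list(per_trait_mean)
    for i in range(bins.size):
        combined[i], combined_se[i] = ivw_combine(
            [per_trait_mean[t][i] for t in traits],
            [per_trait_se[t][i] for t in traits],
        )
    scale = combined.mean() if normalize == "mean" else combined.sum()
    if scale == 0:
        raise ValueError("combined enrichments normalize to zero")
    return pd.DataFrame({
        "bin": bins,
        "enrichment": combined / scale,
        "se": combined_se / abs(scale),
        "n_traits": len(traits),
    })
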