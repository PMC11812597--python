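"""Closed-form quantities of the stabilizing-selection association model.

A variant has per-trait effects ``alpha_t`` (a gene's loss-of-function
burden has effects ``gamma_t``), with trait 1 the trait under study.
*Trait importance* is the squared focal effect; *trait specificity* is the
focal squared effect over the summed squared effects across all
fitness-relevant traits (``Psi_V`` for variants, ``Psi_G`` for genes).
Under stabilizing selection the heterozygote selection coefficient is
approximately the summed importance, ``s_het ~ sum_t gamma_t^2``, which
couples association-test power to specificity rather than importance.

All "proportional to" results carry an explicit scale constant defaulting
to one; p-values follow the two-sided convention via the 1-df chi-square
upper tail.  Functions are vectorized over array inputs.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import chi2

from .popgen import SelectionGrid, distribution_moments, nearest_index

__all__ = [
    "EffectVector",
    "SummaryRecord",
    "trait_specificity",
    "unbiased_importance",
    "expected_burden_strength",
    "expected_plof_product",
    "realized_heritability",
    "heritability_proxy",
    "bonferroni_threshold",
    "flattening_curve",
    "pvalue_from_z_sq",
]


class EffectVector:
    """Per-trait squared effects of a variant (``alpha_t^2``) or gene (``gamma_t^2``).

    Parameters
    ----------
    squared_effects : array-like
        Non-negative squared effects, one per fitness-relevant trait, in
        standardized-trait units squared.
    focal_index : int
        Index of the trait under study (trait 1 of the model).
    """

    def __init__(self, squared_effects, focal_index: int = 0):
        sq = np.asarray(squared_effects, dtype=float)
        if sq.ndim != 1 or sq.size == 0:
            raise ValueError("squared_effects must be a non-empty 1-d array")
        if not np.all(np.isfinite(sq)) or np.any(sq < 0):
            raise ValueError("squared effects must be finite and non-negative")
        if not (0 <= focal_index < sq.size):
            raise ValueError("focal_index out of range")
        self.squared_effects = sq
        self.focal_index = int(focal_index)

    @property
    def total(self) -> float:
        """Summed squared effects across traits (the selection coupling)."""
        return float(self.squared_effects.sum())

    @property
    def focal(self) -> float:
        return float(self.squared_effects[self.focal_index])

    def specificity(self) -> float:
        return trait_specificity(self)


class SummaryRecord:
    """A single association-test summary: estimate, standard error, p-value.

    The p-value, when supplied, must be consistent with the two-sided 1-df
    chi-square of ``(estimate / se)^2`` within 1e-6.
    """

    def __init__(self, estimate: float, se: float, p_value: float | None = None,
                 id: str | None = None):
        if not (se > 0 and np.isfinite(se)):
            raise ValueError("se must be positive and finite")
        if not np.isfinite(estimate):
            raise ValueError("estimate must be finite")
        self.estimate = float(estimate)
        self.se = float(se)
        self.id = id
        implied = float(pvalue_from_z_sq(self.z_sq))
        if p_value is None:
            p_value = implied
        else:
            if not (0.0 < p_value <= 1.0):
                raise ValueError("p_value must be in (0, 1]")
            if abs(p_value - implied) > 1e-6:
                raise ValueError(
                    f"p_value {p_value} inconsistent with z^2={self.z_sq:.6g} "
                    f"(implies {implied:.6g})"
                )
        self.p_value = float(p_value)

    @property
    def z_sq(self) -> float:
        return (self.estimate / self.se) ** 2


def pvalue_from_z_sq(z_sq):
    """Two-sided p-value from a squared z-score (1-df chi-square upper tail)."""
    return chi2.sf(z_sq, df=1)


def trait_specificity(effects: EffectVector) -> float:
    """Focal squared effect over the summed squared effects, in [0, 1]."""
    total = effects.total
    if total <= 0:
        raise ValueError("trait specificity undefined for an all-zero effect vector")
    return effects.focal / total


def unbiased_importance(record: SummaryRecord | None = None, *,
                        estimate=None, se=None):
    """Unbiased estimate of the squared effect: ``estimate^2 - se^2``.

    With the estimate Normal about its true value, squaring is biased
    upward by the sampling variance; subtracting ``se^2`` removes the bias.
    The result may be negative — unbiasedness, not positivity, is the
    contract.  Accepts a :class:`SummaryRecord` or arrays via keywords.
    """
    if record is not None:
        estimate, se = record.estimate, record.se
    estimate = np.asarray(estimate, dtype=float)
    se = np.asarray(se, dtype=float)
    out = estimate**2 - se**2
    return float(out) if out.ndim == 0 else out


def expected_burden_strength(gamma1_sq, p_lof, scale: float = 1.0):
    """Relative expected burden-test ``z^2``: ``gamma_1^2 * p_lof * (1 - p_lof)``.

    Interpreted up to a study-wide constant (sample size, phenotype scale).
    """
    gamma1_sq = np.asarray(gamma1_sq, dtype=float)
    p_lof = np.asarray(p_lof, dtype=float)
    if np.any((p_lof < 0) | (p_lof > 1)):
        raise ValueError("p_lof must be in [0, 1]")
    if np.any(gamma1_sq < 0):
        raise ValueError("gamma1_sq must be non-negative")
    out = scale * gamma1_sq * p_lof * (1.0 - p_lof)
    return float(out) if out.ndim == 0 else out


def expected_plof_product(mu, length, s_het, scale_c: float = 1.0):
    """Expected ``p_lof (1 - p_lof)`` at mutation-selection balance.

    For sufficiently strong selection the aggregate loss-of-function
    frequency satisfies ``p_lof (1 - p_lof) ~ c * mu * L / s_het`` where
    ``mu`` is the per-base mutation rate and ``L`` the number of sites at
    which an LoF can arise.  Clipped to the feasible range [0, 0.25].
    """
    mu = np.asarray(mu, dtype=float)
    length = np.asarray(length, dtype=float)
    s_het = np.asarray(s_het, dtype=float)
    if np.any(mu <= 0) or np.any(length <= 0) or np.any(s_het <= 0) or scale_c <= 0:
        raise ValueError("mu, length, s_het and scale_c must all be positive")
    out = np.clip(scale_c * mu * length / s_het, 0.0, 0.25)
    return float(out) if out.ndim == 0 else out


def realized_heritability(alpha1_sq, p):
    """A variant's realized contribution to heritability: ``2 alpha_1^2 p (1-p)``."""
    alpha1_sq = np.asarray(alpha1_sq, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency must be in [0, 1]")
    out = 2.0 * alpha1_sq * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def heritability_proxy(z_sq):
    """Heritability proxy from a squared z-score: ``z^2 - 1``.

    Has expectation zero under the null (1-df chi-square mean is one) and is
    proportional to the contributed heritability otherwise; negative values
    are retained.
    """
    z_sq = np.asarray(z_sq, dtype=float)
    if np.any(z_sq < 0):
        raise ValueError("z_sq must be non-negative")
    out = z_sq - 1.0
    return float(out) if out.ndim == 0 else out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold ``alpha / n_tests``."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def flattening_curve(alpha2_grid, psi: float, grid: SelectionGrid) -> np.ndarray:
    """Expected realized heritability as a function of the total focal effect.

    For each focal squared effect ``alpha^2`` the implied selection strength
    is ``s_het = alpha^2 / psi`` (from ``sum_t alpha_t^2 = alpha^2 / psi``);
    the expected contribution is then ``2 alpha^2 E[p(1-p)]`` under the
    equilibrium distribution with the nearest grid selection coefficient.
    The curve rises with ``alpha^2`` while selection is weak, then flattens:
    under strong selection ``E[p(1-p)] ~ mu / s_het``, so the plateau is
    ``2 mu psi`` per site, independent of effect size.
    """
    if not (0.0 < psi <= 1.0):
        raise ValueError("psi must be in (0, 1]")
    alpha2_grid = np.asarray(alpha2_grid, dtype=float)
    if np.any(alpha2_grid <= 0) or np.any(np.diff(alpha2_grid) <= 0):
        raise ValueError("alpha2_grid must be positive and ascending")
    s_implied = alpha2_grid / psi
    lo, hi = grid.s_het_values[0], grid.s_het_values[-1]
    if np.any(s_implied < lo) or np.any(s_implied > hi):
        warnings.warn(
            "implied s_het outside the selection grid; clamping to grid range",
            RuntimeWarning, stacklevel=2,
        )
    idx = np.atleast_1d(nearest_index(grid, np.clip(s_implied, lo, hi)))
    e_pq = np.array([distribution_moments(grid.distributions[i])[1] for i in idx])
    return 2.0 * alpha2_grid * e_pq
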