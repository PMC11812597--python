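"""Equilibrium discrete-time Wright-Fisher allele-frequency distributions.

This module computes the stationary distribution of the derived-allele count
in a finite diploid population evolving under

    selection -> one-way mutation -> binomial resampling

per generation.  Selection acts on heterozygotes only by default: both
homozygotes have relative fitness 1 while heterozygous carriers have fitness
``1 - s_het``, the standard approximation for a variant whose trait effects
are under stabilizing selection.  Mutation is one-way (ancestral -> derived),
so the fixed class (count ``2N``) is absorbing; all equilibrium computations
therefore condition on non-fixation: the fixed class is excluded and the
remaining mass renormalized at each solve step, whose fixed point is the
quasi-stationary distribution (the leading left eigenvector of the
transition matrix restricted to non-fixed counts).

The conditioned equilibrium is found by a shift-inverted sparse eigensolve
(with a renormalized power iteration as fallback); a forward simulator of
the identical per-generation update, restarted from its own occupation
measure whenever a fixation is drawn, serves as an independent oracle in
the test suite.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.stats import binom

__all__ = [
    "PopulationParams",
    "FrequencyDistribution",
    "SelectionGrid",
    "ConvergenceError",
    "build_transition_matrix",
    "stationary_distribution",
    "build_selection_grid",
    "nearest_index",
    "nearest_distribution",
    "distribution_moments",
    "sample_frequencies",
    "forward_simulate",
]

#: dimension guard: refuse to build transition matrices above this population size
MAX_N_DIPLOIDS = 100_000

#: binomial row entries below this are zeroed, then the row is renormalized
ROW_TRUNCATION = 1e-12

#: acceptable residual ||pi P - pi||_1 for a converged stationary solution
RESIDUAL_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Raised when the stationary solve does not reach the residual tolerance."""


@dataclass(frozen=True)
class PopulationParams:
    """Population size and mutation rate of the Wright-Fisher model.

    Parameters
    ----------
    n_diploids : int
        Number of diploid individuals (``2 * n_diploids`` haploid copies).
    mut_rate : float
        Per-site, per-generation probability of an ancestral -> derived
        mutation.  Back mutation is ignored (the ancestral allele is known).
    """

    n_diploids: int
    mut_rate: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n_diploids, (int, np.integer)) and self.n_diploids >= 2):
            raise ValueError(f"n_diploids must be an integer >= 2, got {self.n_diploids}")
        if not (0.0 <= self.mut_rate < 0.25):
            # mut_rate = 0 is admitted as a degenerate case for oracle checks
            raise ValueError(f"mut_rate must be in [0, 0.25), got {self.mut_rate}")

    @property
    def n_haploids(self) -> int:
        return 2 * self.n_diploids


@dataclass
class FrequencyDistribution:
    """Probability mass over derived-allele counts ``0 .. 2N``.

    Attributes
    ----------
    params : PopulationParams
    s_het : float
        Selection coefficient against heterozygous carriers.
    mass : ndarray, shape (2N + 1,)
        Probability of each derived-allele count; sums to one.
    conditioned : bool
        Whether the fixed class (count ``2N``) was excluded and the mass
        renormalized (no-fixation conditioning).
    """

    params: PopulationParams
    s_het: float
    mass: np.ndarray
    conditioned: bool = True

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (self.params.n_haploids + 1,):
            raise ValueError("mass must have one entry per count 0..2N")
        if np.any(self.mass < -1e-12):
            raise ValueError("mass entries must be non-negative")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("mass must sum to 1 within 1e-9")
        if self.conditioned and self.mass[-1] != 0.0:
            raise ValueError("conditioned distribution must have zero mass at count 2N")

    @property
    def frequencies(self) -> np.ndarray:
        """Allele frequencies ``count / 2N`` for each count class."""
        n = self.params.n_haploids
        return np.arange(n + 1) / n

    def to_tsv(self) -> str:
        """Serialize to a tab-separated table (count, frequency, mass).

        The header line records the population parameters and ``s_het``.
        """
        buf = io.StringIO()
        buf.write(
            f"# n_diploids={self.params.n_diploids}\tmut_rate={self.params.mut_rate!r}"
            f"\ts_het={self.s_het!r}\tconditioned={self.conditioned}\n"
        )
        buf.write("count\tfrequency\tmass\n")
        freqs = self.frequencies
        for i, m in enumerate(self.mass):
            buf.write(f"{i}\t{freqs[i]:.10g}\t{m:.12g}\n")
        return buf.getvalue()


@dataclass
class SelectionGrid:
    """A log-spaced grid of selection coefficients with their equilibria."""

    s_het_values: np.ndarray
    distributions: list[FrequencyDistribution] = field(repr=False)

    def __post_init__(self) -> None:
        self.s_het_values = np.asarray(self.s_het_values, dtype=float)
        if len(self.s_het_values) != len(self.distributions):
            raise ValueError("one distribution per grid value required")
        if len(self.s_het_values) == 0:
            raise ValueError("grid must be non-empty")
        if np.any(np.diff(self.s_het_values) <= 0):
            raise ValueError("grid values must be strictly increasing")
        params = {d.params for d in self.distributions}
        if len(params) > 1:
            raise ValueError("all grid distributions must share PopulationParams")

    @property
    def params(self) -> PopulationParams:
        return self.distributions[0].params

    def __len__(self) -> int:
        return len(self.s_het_values)


def _post_selection_frequency(p: np.ndarray, s_het: float, genic: bool = False) -> np.ndarray:
    """Derived-allele frequency after viability selection at frequency ``p``.

    Genotype frequencies follow Hardy-Weinberg.  Default fitnesses are
    (1, 1 - s_het, 1) for (ancestral hom., het., derived hom.); with
    ``genic=True`` the derived homozygote has fitness ``1 - 2 s_het``
    (additive/genic selection) instead.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    w_dd = 1.0 - 2.0 * s_het if genic else 1.0
    w_het = 1.0 - s_het
    num = p * p * w_dd + p * q * w_het
    wbar = p * p * w_dd + 2.0 * p * q * w_het + q * q
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wbar > 0.0, num / wbar, 0.0)
    return out


def expected_offspring_frequency(
    params: PopulationParams, s_het: float, genic: bool = False
) -> np.ndarray:
    """Expected next-generation derived frequency for each current count.

    Applies selection then one-way ancestral -> derived mutation; the
    returned array has one entry per count ``0 .. 2N`` and parameterizes the
    binomial resampling step.
    """
    n = params.n_haploids
    p = np.arange(n + 1) / n
    p_sel = _post_selection_frequency(p, s_het, genic=genic)
    return p_sel + (1.0 - p_sel) * params.mut_rate


def build_transition_matrix(
    params: PopulationParams,
    s_het: float,
    genic: bool = False,
    truncation: float = ROW_TRUNCATION,
) -> sparse.csr_matrix:
    """Row-stochastic transition matrix over derived-allele counts.

    Row ``i`` is ``Binomial(2N, p_i'')`` where ``p_i''`` is the post-selection,
    post-mutation frequency implied by current count ``i``.  Entries below
    ``truncation`` are zeroed and each row renormalized, keeping the matrix
    sparse without perturbing the solve beyond the stated tolerance.
    """
    if not (0.0 <= s_het <= 1.0):
        raise ValueError(f"s_het must be in [0, 1], got {s_het}")
    if params.n_diploids > MAX_N_DIPLOIDS:
        raise ValueError(
            f"n_diploids={params.n_diploids} exceeds the supported cap {MAX_N_DIPLOIDS}"
        )
    n = params.n_haploids
    pp = expected_offspring_frequency(params, s_het, genic=genic)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    counts = np.arange(n + 1)
    for i in range(n + 1):
        mean = n * pp[i]
        sd = np.sqrt(max(n * pp[i] * (1.0 - pp[i]), 0.0))
        # +-10 sd covers binomial mass well below the truncation floor; the
        # constant margin handles the Poisson-like regime near the boundaries
        lo = max(0, int(np.floor(mean - 10.0 * sd - 30.0)))
        hi = min(n, int(np.ceil(mean + 10.0 * sd + 30.0)))
        window = counts[lo : hi + 1]
        pmf = binom.pmf(window, n, pp[i])
        keep = pmf >= truncation
        if not np.any(keep):  # degenerate row: keep the modal entry
            keep = pmf == pmf.max()
        w = window[keep]
        v = pmf[keep]
        v = v / v.sum()
        rows.append(np.full(w.shape, i))
        cols.append(w)
        vals.append(v)
    mat = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n + 1, n + 1),
    )
    return mat


def _solve_stationary(mat: sparse.csr_matrix) -> np.ndarray:
    """Stationary row vector of a row-stochastic sparse matrix.

    Solves ``pi (P - I) = 0`` with the normalization ``sum(pi) = 1`` replacing
    one redundant equation; small negative round-off is clipped.
    """
    n = mat.shape[0]
    a = (mat.T - sparse.identity(n, format="csr")).tocoo()
    keep = a.row != n - 1  # replace the last equation with the normalization
    row = np.concatenate([a.row[keep], np.full(n, n - 1)])
    col = np.concatenate([a.col[keep], np.arange(n)])
    val = np.concatenate([a.data[keep], np.ones(n)])
    lhs = sparse.csc_matrix((val, (row, col)), shape=(n, n))
    rhs = np.zeros(n)
    rhs[n - 1] = 1.0
    pi = spsolve(lhs, rhs)
    pi = np.clip(pi, 0.0, None)
    total = pi.sum()
    if not np.isfinite(total) or total <= 0:
        raise ConvergenceError("stationary solve produced a degenerate solution")
    pi /= total
    residual = float(np.abs(pi @ mat - pi).sum())
    if residual > RESIDUAL_TOL:
        raise ConvergenceError(f"stationary solve residual {residual:.3g} > {RESIDUAL_TOL}")
    return pi


def _leading_left_eigvec(sub: sparse.csr_matrix, max_iter: int = 1_000_000) -> np.ndarray:
    """Leading left eigenvector (quasi-stationary law) of a substochastic matrix.

    Uses ARPACK with shift-invert just above the unit circle for speed; if
    that fails, falls back to the renormalized power iteration
    ``v <- v P / ||v P||_1`` with residual tolerance 1e-10.
    """
    n = sub.shape[0]
    v0 = np.full(n, 1.0 / n)
    vec = None
    if n >= 5:
        try:
            _, vecs = sparse.linalg.eigs(
                sub.T.tocsc(), k=1, sigma=1.0 + 1e-6, which="LM",
                v0=v0, tol=1e-13, maxiter=10_000,
            )
            vec = np.real(vecs[:, 0])
        except Exception:
            vec = None
    if vec is None:
        vec = v0.copy()
        for _ in range(max_iter):
            nxt = vec @ sub
            total = nxt.sum()
            if total <= 0:
                raise ConvergenceError("mass vanished during power iteration")
            nxt /= total
            if np.abs(nxt - vec).sum() < 1e-10:
                vec = nxt
                break
            vec = nxt
        else:
            raise ConvergenceError(f"power iteration did not converge in {max_iter} steps")
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    total = vec.sum()
    if not np.isfinite(total) or total <= 0:
        raise ConvergenceError("eigensolve produced a degenerate quasi-stationary vector")
    vec /= total
    lam = float(vec @ (sub @ np.ones(n)))  # Rayleigh-style absorption-adjusted eigenvalue
    resid = float(np.abs(vec @ sub - lam * vec).sum())
    if resid > RESIDUAL_TOL:
        raise ConvergenceError(f"quasi-stationary residual {resid:.3g} > {RESIDUAL_TOL}")
    return vec


def stationary_distribution(
    params: PopulationParams,
    s_het: float,
    condition_no_fix: bool = True,
    genic: bool = False,
) -> FrequencyDistribution:
    """Equilibrium allele-frequency distribution under the DTWF update.

    With ``condition_no_fix`` (the default, and the only regime with a
    non-degenerate equilibrium under one-way mutation) the fixed class is
    excluded and the mass renormalized at each solve step; the fixed point
    is the quasi-stationary distribution of the restricted chain.
    """
    mat = build_transition_matrix(params, s_het, genic=genic)
    n = params.n_haploids
    if condition_no_fix:
        sub = mat[:n, :n].tocsr()
        pi_sub = _leading_left_eigvec(sub)
        mass = np.zeros(n + 1)
        mass[:n] = pi_sub
    else:
        mass = _solve_stationary(mat)
    return FrequencyDistribution(params=params, s_het=float(s_het), mass=mass,
                                 conditioned=condition_no_fix)


def build_selection_grid(
    params: PopulationParams,
    n_points: int = 50,
    lo: float = 1e-7,
    hi: float = 0.05,
    condition_no_fix: bool = True,
    genic: bool = False,
) -> SelectionGrid:
    """Log-uniform grid of selection coefficients with equilibria.

    Defaults follow the production setup: 50 values from 1e-7 to 0.05 evenly
    spaced on the log scale, endpoints included.
    """
    if lo <= 0:
        raise ValueError("lo must be positive for log spacing")
    if not (lo < hi):
        raise ValueError("require lo < hi")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    values = np.geomspace(lo, hi, n_points)
    values[0], values[-1] = lo, hi  # exact endpoints
    dists = [
        stationary_distribution(params, s, condition_no_fix=condition_no_fix, genic=genic)
        for s in values
    ]
    return SelectionGrid(s_het_values=values, distributions=dists)


def nearest_index(grid: SelectionGrid, s_het) -> np.ndarray | int:
    """Index of the grid value closest to ``s_het`` in log10 distance.

    Values beyond the grid clamp to the nearest endpoint; an exact
    log-midpoint tie resolves to the lower index.  Accepts scalars or arrays.
    """
    if len(grid) == 0:
        raise RuntimeError("empty selection grid")
    s = np.asarray(s_het, dtype=float)
    if np.any(s <= 0):
        raise ValueError("s_het must be positive for log-scale lookup")
    log_grid = np.log10(grid.s_het_values)
    dist = np.abs(np.log10(s)[..., None] - log_grid[None, ...] if s.ndim else
                  np.log10(s) - log_grid)
    idx = np.argmin(dist, axis=-1)  # argmin takes the first (lower) index on ties
    return idx if s.ndim else int(idx)


def nearest_distribution(grid: SelectionGrid, s_het: float) -> FrequencyDistribution:
    """The grid equilibrium whose selection coefficient is nearest in log space."""
    return grid.distributions[nearest_index(grid, float(s_het))]


def distribution_moments(dist: FrequencyDistribution) -> tuple[float, float]:
    """Return ``(E[p], E[p(1-p)])`` of an allele-frequency distribution."""
    p = dist.frequencies
    mean_p = float(np.dot(dist.mass, p))
    mean_pq = float(np.dot(dist.mass, p * (1.0 - p)))
    return mean_p, mean_pq


def sample_frequencies(
    dist: FrequencyDistribution, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` independent allele frequencies (``count / 2N``) from ``dist``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.choice(len(dist.mass), size=n, p=dist.mass)
    return counts / dist.params.n_haploids


def forward_simulate(
    params: PopulationParams,
    s_het: float,
    n_generations: int,
    seed: int | np.random.Generator,
    burn_in: int = 0,
    start_count: int = 0,
    condition_no_fix: bool = True,
    genic: bool = False,
) -> np.ndarray:
    """Empirical count distribution from a generation-by-generation simulation.

    Runs the identical selection -> mutation -> binomial update as the
    transition matrix, but by direct sampling (no matrix is built), recording
    the occupancy of each count after ``burn_in`` generations.  Under
    ``condition_no_fix``, a draw landing in the fixed class restarts the
    trajectory from a state sampled uniformly from its own past (the
    occupation measure), a resampling scheme whose empirical law converges
    to the quasi-stationary distribution.  Serves as an independent oracle
    for :func:`stationary_distribution`.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    n = params.n_haploids
    if not (0 <= start_count <= n):
        raise ValueError("start_count must be in [0, 2N]")
    rng = np.random.default_rng(seed)
    pp = expected_offspring_frequency(params, s_het, genic=genic)
    total = burn_in + n_generations
    history = np.empty(total, dtype=np.int64)
    occupancy = np.zeros(n + 1, dtype=np.int64)
    state = int(start_count)
    for gen in range(total):
        nxt = int(rng.binomial(n, pp[state]))
        if condition_no_fix and nxt == n:
            # restart from the occupation measure of the trajectory so far
            nxt = int(history[rng.integers(gen)]) if gen > 0 else int(start_count)
        state = nxt
        history[gen] = state
        if gen >= burn_in:
            occupancy[state] += 1
    return occupancy / occupancy.sum()
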