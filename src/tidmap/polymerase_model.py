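"""Probabilistic contact-map models driven by RNA-polymerase occupancy.

The models decompose contacts at bin ``i`` into a fraction ``C_i``
mediated by polymerases and ``1 - C_i`` mediated by other proteins, with
``C`` the ChIP occupancy profile normalized so that its maximum equals a
single free parameter ``epsilon`` (maximum polymerase occupancy, in
(0, 1]).  Two hypotheses about polymerase-mediated contacts are modeled:

* **variant 1** — any two polymerases interact preferentially::

      w1(i, j) = C_i * C_j + (1 - C_i) * (1 - C_j)

* **variant 2** — polymerases interact but also insulate, through the
  factor ``m``, the total occupancy strictly between the two bins::

      w2(i, j) = m * C_i * C_j + (1 - C_i) * (1 - C_j),
      m = sum_{n = i+1}^{j-1} C_n          (m = 0 for adjacent/self pairs)

The expected map is ``p(s_ij) * w(i, j)`` with ``p`` the empirical
distance decay, normalized to a doubly stochastic matrix so that entries
are contact probabilities.  ``epsilon`` is fitted over a grid, by
default by maximizing the Poisson likelihood of the raw counts (the
amplitude of the occupancy signature scales with powers of epsilon, so a
scale-aware objective resolves it finely); maximizing the Spearman rank
correlation between balanced observed and model maps — the classical
scoring, which is amplitude-invariant and therefore only coarsely
informative about epsilon — is available as an alternative objective and
is always reported for model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from tidmap.contact_map import ContactMap, DistanceDecay

__all__ = [
    "OccupancyTrack",
    "ModelFit",
    "normalize_chip",
    "model_weights",
    "model_map",
    "doubly_stochastic",
    "fit_epsilon",
    "compare_variants",
]

DEFAULT_EPSILON_GRID = tuple(np.round(np.arange(0.01, 1.001, 0.01), 2))


@dataclass
class OccupancyTrack:
    """Per-bin polymerase occupancy ``C_i`` scaled so ``max = epsilon``."""

    values: np.ndarray
    epsilon: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("occupancy values must lie in [0, 1]")


@dataclass
class ModelFit:
    """Result of an epsilon grid search for one model variant.

    ``objective_per_epsilon`` is the fitted objective along the grid
    (Poisson log-likelihood or Spearman rho, per ``objective``);
    ``spearman_per_epsilon`` holds the rank-correlation curve where it was
    evaluated (the full grid under the Spearman objective, the best-fit
    epsilon only under the likelihood objective) and ``best_spearman`` its
    maximum.
    """

    variant: int
    epsilon_grid: np.ndarray
    objective: str
    objective_per_epsilon: np.ndarray
    best_epsilon: float
    spearman_per_epsilon: np.ndarray
    best_spearman: float
    log_likelihood: float = float("nan")


def normalize_chip(chip: np.ndarray, epsilon: float) -> OccupancyTrack:
    """Scale a nonnegative ChIP track so its maximum equals ``epsilon``."""
    chip = np.asarray(chip, dtype=float)
    if np.any(chip < 0):
        raise ValueError("ChIP signal must be nonnegative")
    peak = chip.max(initial=0.0)
    if peak == 0:
        warnings.warn("all-zero ChIP track; occupancy is identically zero",
                      stacklevel=2)
        return OccupancyTrack(values=np.zeros_like(chip), epsilon=epsilon)
    return OccupancyTrack(values=chip * (epsilon / peak), epsilon=epsilon)


def _intervening_sum(c: np.ndarray, circular: bool) -> np.ndarray:
    """Matrix m[i, j] = sum of c strictly between i and j.

    The sum runs along the arc that realizes the genomic separation (the
    shorter one on circular genomes; the increasing-index arc on ties and
    on linear genomes).  ``m[i, i] = 0`` and ``m`` is symmetric.
    """
    n = len(c)
    cs = np.concatenate([[0.0], np.cumsum(c)])  # cs[k] = sum c[0:k]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    inner = cs[hi] - cs[np.minimum(lo + 1, hi)]
    # inner = sum c[lo+1 : hi] (zero when hi <= lo+1)
    if not circular:
        return inner
    total = cs[-1]
    outer = total - inner - c[lo] - c[hi]
    d = hi - lo
    use_outer = (n - d) < d
    return np.where(use_outer, outer, inner)


def model_weights(c: np.ndarray, variant: int, circular: bool = True) -> np.ndarray:
    """Pairwise contact weights w(i, j) for a given occupancy vector."""
    c = np.asarray(c, dtype=float)
    cc = np.outer(c, c)
    qq = np.outer(1.0 - c, 1.0 - c)
    if variant == 1:
        return cc + qq
    if variant == 2:
        m = _intervening_sum(c, circular)
        return m * cc + qq
    raise ValueError("variant must be 1 or 2")


def doubly_stochastic(
    matrix: np.ndarray, tol: float = 1e-8, max_iter: int = 5000
) -> np.ndarray:
    """Symmetric Sinkhorn scaling to unit row and column sums.

    Each iteration divides ``M[i, j]`` by ``sqrt(r_i * r_j)`` where ``r``
    are the current row sums; for a symmetric nonnegative matrix with
    support this converges to a doubly stochastic matrix.  Zero rows are
    rejected; non-convergence within ``max_iter`` warns and returns the
    partial result.
    """
    matrix = np.asarray(matrix, dtype=float).copy()
    if np.any(matrix < 0):
        raise ValueError("matrix must be nonnegative")
    r = matrix.sum(axis=1)
    if np.any(r == 0):
        raise ValueError("matrix has a zero row; cannot be doubly stochastic")
    for _ in range(max_iter):
        if np.max(np.abs(r - 1.0)) < tol and np.max(np.abs(matrix.sum(axis=0) - 1.0)) < tol:
            return matrix
        s = np.sqrt(r)
        matrix /= s[:, None]
        matrix /= s[None, :]
        r = matrix.sum(axis=1)
    if np.max(np.abs(r - 1.0)) >= tol:
        warnings.warn(f"Sinkhorn did not reach tol={tol} in {max_iter} iterations",
                      stacklevel=2)
    return matrix


def expected_map(
    p: DistanceDecay, c: np.ndarray, variant: int, circular: bool = True
) -> np.ndarray:
    """Un-normalized expected map ``p(s_ij) * w(i, j)``."""
    n = len(c)
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    d = np.abs(i - j)
    if circular:
        d = np.minimum(d, n - d)
    return p(d) * model_weights(c, variant, circular)


def model_map(
    p: DistanceDecay, occupancy: OccupancyTrack, variant: int, circular: bool = True
) -> ContactMap:
    """Doubly stochastic model contact map for one variant."""
    mat = doubly_stochastic(expected_map(p, occupancy.values, variant, circular))
    n = len(occupancy.values)
    return ContactMap(
        matrix=mat,
        bin_size=p.bin_size,
        genome_length=n * p.bin_size,
        circular=circular,
        balanced=True,
    )


def _fit_support(n: int, max_sep_bins: int | None, circular: bool, mask):
    """Upper-triangle (i < j) index pairs used for model fitting."""
    iu, ju = np.triu_indices(n, k=1)
    d = ju - iu
    if circular:
        d = np.minimum(d, n - d)
    keep = np.ones(len(iu), dtype=bool)
    if max_sep_bins is not None:
        keep &= d <= max_sep_bins
    if mask:
        bad = np.zeros(n, dtype=bool)
        bad[list(mask)] = True
        keep &= ~bad[iu] & ~bad[ju]
    return iu[keep], ju[keep]


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra = rankdata(a)
    rb = rankdata(b)
    ra -= ra.mean()
    rb -= rb.mean()
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    return float(ra @ rb / denom) if denom > 0 else float("nan")


def spearman_vs_model(
    balanced: ContactMap,
    chip: np.ndarray,
    p: DistanceDecay,
    variant: int,
    epsilon: float,
    max_sep_bins: int | None = 200,
) -> float:
    """Spearman rho between a balanced observed map and one model map.

    Computed over unmasked upper-triangle pairs within ``max_sep_bins``
    (diagonal excluded), the comparison used to score a fitted model
    against the experiment.
    """
    n = balanced.n_bins
    iu, ju = _fit_support(n, max_sep_bins, balanced.circular, balanced.mask)
    obs = balanced.matrix[iu, ju]
    ok = np.isfinite(obs)
    iu, ju, obs = iu[ok], ju[ok], obs[ok]
    occ = normalize_chip(chip, epsilon)
    mat = doubly_stochastic(expected_map(p, occ.values, variant, balanced.circular))
    return _spearman(obs, mat[iu, ju])


def fit_epsilon(
    observed: ContactMap,
    chip: np.ndarray,
    p: DistanceDecay,
    variant: int,
    grid=DEFAULT_EPSILON_GRID,
    max_sep_bins: int | None = 200,
    objective: str = "likelihood",
    balanced: ContactMap | None = None,
) -> ModelFit:
    """Grid search for the maximum occupancy ``epsilon``.

    Two objectives are available:

    * ``"likelihood"`` (default) — ``observed`` must be the *raw* count
      map; for every epsilon the un-normalized expected map is scaled to
      the observed total and scored by the Poisson log-likelihood over
      the fitting support.  This objective is sensitive to the amplitude
      of the occupancy signature (which scales with powers of epsilon)
      and therefore resolves epsilon finely.  When a ``balanced`` map is
      supplied (or ``observed`` itself is balanced) the Spearman rho of
      the best model is also evaluated and reported.
    * ``"spearman"`` — ``observed`` must be the *balanced* map; for every
      epsilon the doubly stochastic model map is built and scored by
      Spearman rank correlation, and the argmax is returned.  Rank
      correlation is invariant to the amplitude of the occupancy term, so
      this reproduces the classical scoring but resolves epsilon only
      coarsely; it is kept for model comparison and compatibility.

    The support is all unmasked upper-triangle pairs with separation at
    most ``max_sep_bins`` bins (``None`` for the full matrix; the
    diagonal is always excluded).
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid > 1):
        raise ValueError("epsilon grid must lie in (0, 1]")
    n = observed.n_bins
    if len(chip) != n:
        raise ValueError("ChIP track and map must share binning")
    iu, ju = _fit_support(n, max_sep_bins, observed.circular, observed.mask)
    obs_vals = observed.matrix[iu, ju]
    finite = np.isfinite(obs_vals)
    iu, ju, obs_vals = iu[finite], ju[finite], obs_vals[finite]
    if obs_vals.size < 3 or np.ptp(obs_vals) == 0:
        raise ValueError("observed map is degenerate over the fitting support")

    if objective == "spearman":
        obs_ranks = rankdata(obs_vals)
        obs_ranks -= obs_ranks.mean()
        obs_norm = np.sqrt((obs_ranks**2).sum())
        curve = np.empty(len(grid))
        for k, eps in enumerate(grid):
            occ = normalize_chip(chip, float(eps))
            mat = doubly_stochastic(
                expected_map(p, occ.values, variant, observed.circular)
            )
            mod_ranks = rankdata(mat[iu, ju])
            mod_ranks -= mod_ranks.mean()
            denom = obs_norm * np.sqrt((mod_ranks**2).sum())
            curve[k] = (obs_ranks @ mod_ranks) / denom if denom > 0 else np.nan
        best = int(np.nanargmax(curve))
        return ModelFit(
            variant=variant,
            epsilon_grid=grid,
            objective="spearman",
            objective_per_epsilon=curve,
            best_epsilon=float(grid[best]),
            spearman_per_epsilon=curve,
            best_spearman=float(curve[best]),
        )
    if objective != "likelihood":
        raise ValueError("objective must be 'likelihood' or 'spearman'")

    # Poisson likelihood on raw counts; epsilon enters the pair weights as
    #   w1 = 1 - eps*(si+sj) + 2*eps^2*si*sj
    #   w2 = 1 - eps*(si+sj) +   eps^2*si*sj + eps^3*mhat*si*sj
    # with s the unit-max ChIP shape and mhat the intervening shape sum,
    # so the support vectors are precomputed once.
    chip = np.asarray(chip, dtype=float)
    peak = chip.max(initial=0.0)
    shape = chip / peak if peak > 0 else np.zeros_like(chip)
    d = ju - iu
    if observed.circular:
        d = np.minimum(d, n - d)
    pvec = p(d)
    s1 = shape[iu] + shape[ju]
    s2 = shape[iu] * shape[ju]
    if variant == 2:
        mhat = _intervening_sum(shape, observed.circular)[iu, ju]
    total = obs_vals.sum()
    curve = np.empty(len(grid))
    for k, eps in enumerate(grid):
        if variant == 1:
            w = 1.0 - eps * s1 + 2.0 * eps**2 * s2
        else:
            w = 1.0 - eps * s1 + eps**2 * s2 + eps**3 * mhat * s2
        mu = pvec * w
        mu *= total / mu.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            curve[k] = float(np.sum(obs_vals * np.log(mu)) - total)
    best = int(np.nanargmax(curve))
    best_eps = float(grid[best])
    spearman_curve = np.full(len(grid), np.nan)
    best_spearman = float("nan")
    score_map = balanced if balanced is not None else (
        observed if observed.balanced else None
    )
    if score_map is not None:
        best_spearman = spearman_vs_model(
            score_map, chip, p, variant, best_eps, max_sep_bins
        )
        spearman_curve[best] = best_spearman
    return ModelFit(
        variant=variant,
        epsilon_grid=grid,
        objective="likelihood",
        objective_per_epsilon=curve,
        best_epsilon=best_eps,
        spearman_per_epsilon=spearman_curve,
        best_spearman=best_spearman,
        log_likelihood=float(curve[best]),
    )


def compare_variants(
    observed: ContactMap,
    chip: np.ndarray,
    p: DistanceDecay,
    grid=DEFAULT_EPSILON_GRID,
    max_sep_bins: int | None = 200,
    objective: str = "likelihood",
    balanced: ContactMap | None = None,
) -> dict[int, ModelFit]:
    """Fit both model variants for model selection.

    Under the likelihood objective the preferred variant is the one with
    the larger maximized log-likelihood (the curves are directly
    comparable: same data, same support, same number of free
    parameters); each fit also carries the Spearman rho of its best
    model when a balanced map is available.
    """
    return {
        v: fit_epsilon(observed, chip, p, v, grid=grid, max_sep_bins=max_sep_bins,
                       objective=objective, balanced=balanced)
        for v in (1, 2)
    }
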