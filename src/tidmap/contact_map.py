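"""Contact-map container, I/O and matrix-level preprocessing.

A :class:`ContactMap` is a symmetric ``N x N`` matrix of contact counts (or
balanced contact frequencies) over a binned, usually circular, bacterial
genome, together with a mask of invalid ("white line") bins.  The functions
here cover the standard preprocessing steps applied before any domain
calling: ICE balancing, low-coverage bin masking, downsampling to a common
contact number, log2 map comparison, distance-decay estimation, rebinning
and row-correlation matrices.

Coordinates are 0-based and half-open; bin ``i`` covers
``[i * bin_size, (i + 1) * bin_size)``.  For circular genomes the genomic
separation between bins ``i`` and ``j`` is ``min(|i - j|, N - |i - j|)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ContactMap",
    "DistanceDecay",
    "read_map",
    "write_map",
    "ice_balance",
    "detect_white_lines",
    "downsample",
    "log2_ratio",
    "distance_decay",
    "rebin",
    "correlation_matrix",
]

_SYM_RTOL = 1e-9


@dataclass
class ContactMap:
    """Symmetric binned genome contact matrix.

    Parameters
    ----------
    matrix:
        ``N x N`` nonnegative array of raw counts or balanced frequencies.
    bin_size:
        Bin width in bp.
    genome_length:
        Genome length in bp; ``N == ceil(genome_length / bin_size)``.
    circular:
        Whether the genome is circular (bacterial chromosomes are).
    mask:
        Indices of invalid bins excluded from all computations.
    balanced:
        True once the map has been ICE-balanced.
    """

    matrix: np.ndarray
    bin_size: int
    genome_length: int
    circular: bool = True
    mask: frozenset[int] = field(default_factory=frozenset)
    balanced: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError(f"contact matrix must be square, got {self.matrix.shape}")
        n_expected = -(-int(self.genome_length) // int(self.bin_size))
        if self.matrix.shape[0] != n_expected:
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} bins but genome_length/bin_size "
                f"implies {n_expected}"
            )
        finite = np.isfinite(self.matrix)
        if np.any(self.matrix[finite] < 0):
            raise ValueError("contact matrix contains negative values")
        scale = max(np.abs(self.matrix[finite]).max(initial=0.0), 1.0)
        asym = np.nanmax(np.abs(self.matrix - self.matrix.T), initial=0.0)
        if asym > _SYM_RTOL * scale:
            raise ValueError(f"contact matrix is asymmetric (max |M - M.T| = {asym:g})")
        self.mask = frozenset(int(i) for i in self.mask)
        if any(i < 0 or i >= self.n_bins for i in self.mask):
            raise ValueError("mask indices out of range")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def mask_array(self) -> np.ndarray:
        """Boolean array, True at invalid bins."""
        out = np.zeros(self.n_bins, dtype=bool)
        if self.mask:
            out[list(self.mask)] = True
        return out

    def valid_bins(self) -> np.ndarray:
        """Sorted indices of unmasked bins."""
        return np.flatnonzero(~self.mask_array())

    def separation(self, i, j):
        """Genomic separation in bins, wrapping on circular genomes."""
        d = np.abs(np.asarray(i) - np.asarray(j))
        if self.circular:
            d = np.minimum(d, self.n_bins - d)
        return d

    def separation_matrix(self) -> np.ndarray:
        idx = np.arange(self.n_bins)
        return self.separation(idx[:, None], idx[None, :])

    def total_contacts(self) -> float:
        """Total contacts counting each unordered pair once (diagonal once)."""
        iu = np.triu_indices(self.n_bins)
        vals = self.matrix[iu]
        return float(np.nansum(vals))

    def copy(self) -> "ContactMap":
        return replace(self, matrix=self.matrix.copy())


@dataclass
class DistanceDecay:
    """Mean contact frequency p(s) per genomic separation s (in bins)."""

    separations: np.ndarray
    values: np.ndarray
    bin_size: int = 1

    def __post_init__(self) -> None:
        self.separations = np.asarray(self.separations, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.separations.shape != self.values.shape:
            raise ValueError("separations and values must have equal length")
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise ValueError("p(s) values must be nonnegative")

    def __call__(self, s):
        """Evaluate p at separation(s) ``s`` (bins), clipping to the range."""
        s = np.clip(np.asarray(s, dtype=int), self.separations.min(), self.separations.max())
        lookup = np.full(self.separations.max() + 1, np.nan)
        lookup[self.separations] = self.values
        return lookup[s]


# ---------------------------------------------------------------------------
# I/O: dense TSV with header lines, sparse upper-triangle triplet TSV
# ---------------------------------------------------------------------------


def _parse_header(path: str) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    for key in ("bin_size", "genome_length", "circular"):
        if key not in meta:
            raise ValueError(f"missing required header line '#{key}=' in {path}")
    return {
        "bin_size": int(meta["bin_size"]),
        "genome_length": int(meta["genome_length"]),
        "circular": meta["circular"].lower() in ("1", "true", "yes"),
        "balanced": meta.get("balanced", "false").lower() in ("1", "true", "yes"),
        "mask": frozenset(
            int(x) for x in meta.get("mask", "").split(",") if x.strip() != ""
        ),
    }


def read_map(path: str, format: str = "auto") -> ContactMap:
    """Read a contact map from dense-TSV or sparse triplet-TSV text.

    Both formats carry ``#bin_size=``, ``#genome_length=`` and ``#circular=``
    header lines (optionally ``#mask=`` and ``#balanced=``).  Triplet rows are
    ``bin_i <TAB> bin_j <TAB> value`` over one triangle; values are mirrored
    into both triangles.  A dense input asymmetric beyond 1e-9 relative
    tolerance, or any negative value, is rejected.
    """
    meta = _parse_header(path)
    n = -(-meta["genome_length"] // meta["bin_size"])
    body = np.loadtxt(path, comments="#", ndmin=2)
    if body.size == 0:
        matrix = np.zeros((n, n))
    elif format == "triplet" or (format == "auto" and body.shape[1] == 3):
        matrix = np.zeros((n, n))
        i = body[:, 0].astype(int)
        j = body[:, 1].astype(int)
        if np.any(i < 0) or np.any(j < 0) or np.any(i >= n) or np.any(j >= n):
            raise ValueError("triplet bin index out of range")
        if np.any(body[:, 2] < 0):
            raise ValueError("negative contact value in triplet input")
        np.add.at(matrix, (i, j), body[:, 2])
        lower = i != j
        np.add.at(matrix, (j[lower], i[lower]), body[lower, 2])
    else:
        matrix = body
        if matrix.shape != (n, n):
            raise ValueError(f"dense matrix shape {matrix.shape} != ({n}, {n})")
    return ContactMap(
        matrix=matrix,
        bin_size=meta["bin_size"],
        genome_length=meta["genome_length"],
        circular=meta["circular"],
        mask=meta["mask"],
        balanced=meta["balanced"],
    )


def write_map(cmap: ContactMap, path: str, format: str = "triplet") -> None:
    """Write a contact map as triplet (upper triangle) or dense TSV."""
    with open(path, "w") as fh:
        fh.write(f"#bin_size={cmap.bin_size}\n")
        fh.write(f"#genome_length={cmap.genome_length}\n")
        fh.write(f"#circular={str(cmap.circular).lower()}\n")
        fh.write(f"#balanced={str(cmap.balanced).lower()}\n")
        if cmap.mask:
            fh.write("#mask=" + ",".join(str(i) for i in sorted(cmap.mask)) + "\n")
        if format == "triplet":
            iu, ju = np.triu_indices(cmap.n_bins)
            vals = cmap.matrix[iu, ju]
            keep = np.isfinite(vals) & (vals != 0)
            for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
                fh.write(f"{i}\t{j}\t{v:.12g}\n")
        elif format == "dense":
            np.savetxt(fh, cmap.matrix, delimiter="\t", fmt="%.12g")
        else:
            raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Balancing and masking
# ---------------------------------------------------------------------------


def _row_sum_cv(matrix: np.ndarray, valid: np.ndarray) -> float:
    sums = matrix[np.ix_(valid, valid)].sum(axis=1)
    mean = sums.mean()
    return float(sums.std() / mean) if mean > 0 else np.inf


def ice_balance(
    cmap: ContactMap, tol: float = 1e-6, max_iter: int = 1000
) -> ContactMap:
    """Iteratively correct a raw map so every unmasked bin has equal visibility.

    Symmetric iterative correction: each round divides ``M[i, j]`` by
    ``sqrt(b_i * b_j)`` where ``b_i`` is the bin's row sum relative to the
    mean, until the coefficient of variation of unmasked row sums falls
    below ``tol``.  The mean row sum (and the total) is preserved.  All-zero
    unmasked rows are added to the mask with a warning; non-convergence
    within ``max_iter`` yields a warning and the partial result.
    """
    matrix = cmap.matrix.astype(float).copy()
    mask = set(cmap.mask)
    matrix[list(mask), :] = 0.0
    matrix[:, list(mask)] = 0.0
    valid = np.array([i for i in range(cmap.n_bins) if i not in mask])
    zero_rows = valid[matrix[valid].sum(axis=1) == 0]
    if zero_rows.size:
        warnings.warn(
            f"{zero_rows.size} all-zero unmasked row(s) added to mask", stacklevel=2
        )
        mask.update(int(i) for i in zero_rows)
        valid = np.array([i for i in range(cmap.n_bins) if i not in mask])
    if valid.size == 0:
        raise ValueError("no valid bins to balance")

    converged = False
    for _ in range(max_iter):
        if _row_sum_cv(matrix, valid) < tol:
            converged = True
            break
        sums = matrix[np.ix_(valid, valid)].sum(axis=1)
        bias = np.ones(cmap.n_bins)
        bias[valid] = np.sqrt(sums / sums.mean())
        matrix /= bias[:, None]
        matrix /= bias[None, :]
    if not converged and _row_sum_cv(matrix, valid) >= tol:
        warnings.warn(
            f"ICE did not converge to tol={tol} within {max_iter} iterations",
            stacklevel=2,
        )
    return ContactMap(
        matrix=matrix,
        bin_size=cmap.bin_size,
        genome_length=cmap.genome_length,
        circular=cmap.circular,
        mask=frozenset(mask),
        balanced=True,
    )


def detect_white_lines(coverage: np.ndarray) -> frozenset[int]:
    """Flag low-coverage bins: ``coverage < median - 3 * MAD``.

    ``MAD = median(|x - median(x)|)``.  When the MAD is zero (constant-ish
    coverage) the threshold degenerates to ``< median``; a warning is
    emitted because the rule then flags any bin merely below the median.
    """
    coverage = np.asarray(coverage, dtype=float)
    med = float(np.median(coverage))
    mad = float(np.median(np.abs(coverage - med)))
    if mad == 0.0:
        warnings.warn(
            "MAD of coverage is zero; white-line threshold degenerates to "
            "'below median'",
            stacklevel=2,
        )
    threshold = med - 3.0 * mad
    return frozenset(int(i) for i in np.flatnonzero(coverage < threshold))


# ---------------------------------------------------------------------------
# Downsampling and comparison
# ---------------------------------------------------------------------------


def downsample(cmap: ContactMap, n_contacts: int, seed: int) -> ContactMap:
    """Thin a raw count map to exactly ``n_contacts`` total contacts.

    Draws a multivariate hypergeometric sample over the upper-triangle
    counts (sampling contacts without replacement), then mirrors back to a
    symmetric matrix.  Deterministic given ``seed``.
    """
    counts = np.rint(cmap.matrix).astype(np.int64)
    iu, ju = np.triu_indices(cmap.n_bins)
    upper = counts[iu, ju]
    total = int(upper.sum())
    if n_contacts > total:
        raise ValueError(f"n_contacts={n_contacts} exceeds total contacts {total}")
    rng = np.random.default_rng(seed)
    thinned = rng.multivariate_hypergeometric(upper, n_contacts, method="marginals")
    out = np.zeros_like(counts)
    out[iu, ju] = thinned
    out = out + np.triu(out, 1).T
    return replace(cmap, matrix=out.astype(float))


def log2_ratio(
    map_a: ContactMap, map_b: ContactMap, pseudocount: float = 0.0
) -> np.ndarray:
    """Elementwise ``log2((a + pc) / (b + pc))`` between same-shape maps.

    Bins masked in either map propagate as NaN rows/columns.  Inputs are
    expected to have been downsampled to the same number of contacts.
    """
    if map_a.matrix.shape != map_b.matrix.shape:
        raise ValueError("maps have different shapes")
    if map_a.bin_size != map_b.bin_size:
        raise ValueError("maps have different bin sizes")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(map_a.matrix + pseudocount) - np.log2(
            map_b.matrix + pseudocount
        )
    bad = list(map_a.mask | map_b.mask)
    if bad:
        ratio[bad, :] = np.nan
        ratio[:, bad] = np.nan
    return ratio


# ---------------------------------------------------------------------------
# Distance decay, rebinning, correlation
# ---------------------------------------------------------------------------


def distance_decay(cmap: ContactMap) -> DistanceDecay:
    """Mean contact frequency per genomic separation, p(s).

    Averages over unmasked bin pairs at each circular (or linear)
    separation.  Separations at which every pair is masked are filled by
    linear interpolation across neighbouring separations.
    """
    n = cmap.n_bins
    s_max = n // 2 if cmap.circular else n - 1
    sep = cmap.separation_matrix()
    valid = ~cmap.mask_array()
    pair_ok = valid[:, None] & valid[None, :] & np.isfinite(cmap.matrix)
    sel = sep[pair_ok]
    sums = np.bincount(sel, weights=cmap.matrix[pair_ok], minlength=s_max + 1)
    counts = np.bincount(sel, minlength=s_max + 1)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    missing = np.isnan(values)
    if np.any(missing):
        if np.all(missing):
            raise ValueError("no valid pairs at any separation")
        idx = np.arange(s_max + 1)
        values[missing] = np.interp(idx[missing], idx[~missing], values[~missing])
    return DistanceDecay(
        separations=np.arange(s_max + 1), values=values, bin_size=cmap.bin_size
    )


def rebin(cmap: ContactMap, factor: int) -> ContactMap:
    """Coarsen a map by block-summing ``factor x factor`` bin blocks.

    The final partial block (when ``N % factor != 0``) is summed over its
    actual extent.  A coarse bin is masked iff more than half of its
    constituent fine bins are masked.  Total contacts are preserved.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return cmap.copy()
    n = cmap.n_bins
    n_coarse = -(-n // factor)
    block = np.zeros((n_coarse, n))
    for c in range(n_coarse):
        block[c, c * factor : min((c + 1) * factor, n)] = 1.0
    matrix = block @ np.nan_to_num(cmap.matrix) @ block.T
    fine_masked = cmap.mask_array()
    mask = frozenset(
        c
        for c in range(n_coarse)
        if fine_masked[c * factor : min((c + 1) * factor, n)].mean() > 0.5
    )
    return ContactMap(
        matrix=matrix,
        bin_size=cmap.bin_size * factor,
        genome_length=cmap.genome_length,
        circular=cmap.circular,
        mask=mask,
        balanced=cmap.balanced,
    )


def correlation_matrix(cmap: ContactMap, log: bool = False) -> np.ndarray:
    """Pearson correlation between contact-matrix rows.

    Returns an ``N x N`` matrix with unit diagonal; masked bins give NaN
    rows/columns, and the masked columns are excluded from every row vector
    before correlating.  With ``log=True`` rows are log-transformed
    (``log(x + 1)``) first.  Constant rows yield correlation 0 with a
    warning.
    """
    valid = cmap.valid_bins()
    data = np.nan_to_num(cmap.matrix[np.ix_(valid, valid)])
    if log:
        data = np.log1p(data)
    sd = data.std(axis=1)
    const = sd == 0
    if np.any(const):
        warnings.warn(
            f"{const.sum()} constant row(s); correlations set to 0", stacklevel=2
        )
    centered = data - data.mean(axis=1, keepdims=True)
    sd_safe = np.where(const, 1.0, sd)
    corr_valid = (centered @ centered.T) / (data.shape[1] * np.outer(sd_safe, sd_safe))
    corr_valid[const, :] = 0.0
    corr_valid[:, const] = 0.0
    np.fill_diagonal(corr_valid, 1.0)
    corr = np.full((cmap.n_bins, cmap.n_bins), np.nan)
    corr[np.ix_(valid, valid)] = np.clip(corr_valid, -1.0, 1.0)
    return corr
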