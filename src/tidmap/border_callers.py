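"""Domain-boundary calling: directionality index and relative insulation.

Two complementary boundary callers are provided.

**Directionality index (DI).**  For every bin the vectors of correlations
with the ``w`` bins to its left and to its right are compared with a
paired t-test; the per-bin t value quantifies upstream (negative) versus
downstream (positive) contact bias.  Boundaries sit where the t track
switches from a significantly negative run to a significantly positive
run (|t| >= 2, i.e. P < 0.05 for the window sizes used here).

**Multi-window relative insulation.**  For a bin ``i`` and window ``w``
let ``A`` and ``B`` be the total contacts within the upstream block
``[i-w, i)`` and downstream block ``[i, i+w)`` and ``C`` the contacts
between the blocks; the relative insulation ``RI = (A+B-C)/(A+B+C)`` is
bounded in [-1, 1], scale-free, and maximal at contact-depleted
junctions.  RI is averaged over a set of window sizes, the second
envelope of the averaged track is removed, and boundaries are local
maxima above a z-score cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from tidmap.contact_map import ContactMap, correlation_matrix
from tidmap.tid_caller import remove_second_envelope

__all__ = [
    "BorderCall",
    "directionality_index",
    "call_di_borders",
    "insulation_multiscale",
    "call_insulation_borders",
    "compare_border_sets",
    "interval_overlap_kb",
]

DEFAULT_INSULATION_WINDOWS_BP = (10_000, 15_000, 20_000, 25_000, 30_000)


@dataclass(frozen=True)
class BorderCall:
    """A called domain boundary and the statistic that supports it."""

    bin: int
    method: str  # "DI" or "insulation"
    statistic: float
    window_bp: tuple[int, ...]


def directionality_index(
    cmap: ContactMap,
    window_bins: int,
    use_correlation: bool = True,
) -> np.ndarray:
    """Per-bin paired-t directionality track.

    For bin ``i`` the left vector is ``corr(i, i-k)`` and the right vector
    ``corr(i, i+k)`` for ``k = 1..w`` (wrapping on circular genomes);
    the paired differences ``d_k = R_k - L_k`` give
    ``t = mean(d) / (sd(d) / sqrt(w))`` with the sample (n-1) standard
    deviation.  Positive t means stronger downstream contacts.  Pairs in
    which either neighbour is masked are dropped; bins with fewer than 2
    usable pairs (or a masked centre) get NaN.  With
    ``use_correlation=False`` raw balanced contacts are used instead of
    correlation-matrix rows.
    """
    if window_bins < 2:
        raise ValueError("window_bins must be >= 2")
    data = correlation_matrix(cmap) if use_correlation else cmap.matrix
    n = cmap.n_bins
    masked = cmap.mask_array()
    t_track = np.full(n, np.nan)
    ks = np.arange(1, window_bins + 1)
    zero_sd = 0
    for i in range(n):
        if masked[i]:
            continue
        li = i - ks
        ri = i + ks
        if cmap.circular:
            li, ri = li % n, ri % n
        else:
            ok = (li >= 0) & (ri < n)
            li, ri = li[ok], ri[ok]
        good = ~masked[li] & ~masked[ri]
        li, ri = li[good], ri[good]
        left = data[i, li]
        right = data[i, ri]
        finite = np.isfinite(left) & np.isfinite(right)
        d = right[finite] - left[finite]
        w = d.size
        if w < 2:
            continue
        sd = d.std(ddof=1)
        # differences at floating-point noise level are degenerate too
        if sd == 0 or np.max(np.abs(d)) < 1e-12:
            t_track[i] = 0.0
            zero_sd += 1
        else:
            t_track[i] = d.mean() / (sd / np.sqrt(w))
    if zero_sd:
        warnings.warn(f"{zero_sd} bin(s) with zero-variance differences; t set to 0",
                      stacklevel=2)
    return t_track


def call_di_borders(
    t_track: np.ndarray,
    t_threshold: float = 2.0,
    max_gap_bins: int = 2,
    window_bp: tuple[int, ...] = (),
) -> list[BorderCall]:
    """Boundaries where DI switches from significantly negative to positive.

    A border is the first bin of a run with ``t >= +threshold`` that
    follows a run with ``t <= -threshold``, allowing at most
    ``max_gap_bins`` non-significant bins between the two runs.  The order
    matters: positive-then-negative transitions are domain interiors, not
    borders.
    """
    t_track = np.asarray(t_track, dtype=float)
    borders = []
    last_neg_end = None  # index just past the last significant-negative bin
    for i, t in enumerate(t_track):
        if not np.isfinite(t):
            continue
        if t <= -t_threshold:
            last_neg_end = i + 1
        elif t >= t_threshold:
            if last_neg_end is not None and (i - last_neg_end) <= max_gap_bins:
                borders.append(
                    BorderCall(bin=i, method="DI", statistic=float(t),
                               window_bp=tuple(window_bp))
                )
            last_neg_end = None  # one border per negative run
    return borders


def _block_indices(i: int, w: int, n: int, circular: bool):
    up = np.arange(i - w, i)
    down = np.arange(i, i + w)
    if circular:
        return up % n, down % n
    if up[0] < 0 or down[-1] >= n:
        return None, None
    return up, down


def relative_insulation(cmap: ContactMap, window_bins: int) -> np.ndarray:
    """Single-window relative insulation RI = (A+B-C)/(A+B+C) per bin.

    A and B count unordered within-block pairs (diagonal excluded), C the
    full between-block rectangle; masked bins are excluded from the
    blocks, and a bin whose blocks are entirely masked gets NaN.
    """
    n = cmap.n_bins
    matrix = np.nan_to_num(cmap.matrix)
    masked = cmap.mask_array()
    ri = np.full(n, np.nan)
    for i in range(n):
        up, down = _block_indices(i, window_bins, n, cmap.circular)
        if up is None:
            continue
        up = up[~masked[up]]
        down = down[~masked[down]]
        if up.size == 0 or down.size == 0:
            continue
        sub_u = matrix[np.ix_(up, up)]
        sub_d = matrix[np.ix_(down, down)]
        a = (sub_u.sum() - np.trace(sub_u)) / 2.0
        b = (sub_d.sum() - np.trace(sub_d)) / 2.0
        c = matrix[np.ix_(up, down)].sum()
        denom = a + b + c
        if denom > 0:
            ri[i] = (a + b - c) / denom
    return ri


def insulation_multiscale(
    cmap: ContactMap,
    windows_bp: tuple[int, ...] = DEFAULT_INSULATION_WINDOWS_BP,
) -> np.ndarray:
    """Average RI over several window sizes and remove its second envelope.

    Returns the corrected insulation track; boundaries are its local
    maxima (see :func:`call_insulation_borders`).  Window sizes are given
    in bp and converted by the map's bin size; windows smaller than one
    bin are rejected.
    """
    window_bins = []
    for w_bp in windows_bp:
        w = int(round(w_bp / cmap.bin_size))
        if w < 1:
            raise ValueError(f"window {w_bp} bp is below one bin ({cmap.bin_size} bp)")
        window_bins.append(w)
    tracks = [relative_insulation(cmap, w) for w in window_bins]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_ri = np.nanmean(np.vstack(tracks), axis=0)
    return remove_second_envelope(mean_ri, circular=cmap.circular)


def call_insulation_borders(
    corrected: np.ndarray,
    z_cutoff: float = 1.0,
    windows_bp: tuple[int, ...] = DEFAULT_INSULATION_WINDOWS_BP,
    circular: bool = True,
) -> list[BorderCall]:
    """Local maxima of the corrected insulation track above a z cutoff.

    A bin is called when it is a strict local maximum (leftmost bin of a
    plateau) and its corrected value is at least
    ``mean + z_cutoff * sd`` of the defined track.
    """
    corrected = np.asarray(corrected, dtype=float)
    m = len(corrected)
    defined = np.isfinite(corrected)
    if defined.sum() < 2:
        return []
    vals = corrected[defined]
    if np.ptp(vals) == 0:
        return []
    cutoff = vals.mean() + z_cutoff * vals.std(ddof=1)
    work = np.where(defined, corrected, -np.inf)

    def _get(i):
        return work[i % m] if circular else (work[i] if 0 <= i < m else -np.inf)

    calls = []
    for i in range(m):
        v = work[i]
        if not defined[i] or v < cutoff:
            continue
        if v > _get(i - 1) and v >= _get(i + 1):
            if v == _get(i + 1):
                j = i + 1
                while _get(j) == v:
                    j += 1
                if _get(j) > v:
                    continue
            calls.append(
                BorderCall(bin=i, method="insulation", statistic=float(v),
                           window_bp=tuple(windows_bp))
            )
    return calls


def compare_border_sets(a, b, tol_bins: int):
    """Greedy nearest matching between two border lists within a tolerance.

    ``a`` and ``b`` are sequences of bin indices or :class:`BorderCall`.
    Candidate pairs are considered by increasing distance; each border is
    matched at most once.  Returns ``(matched, a_only, b_only)`` counts.
    """
    a_bins = sorted(c.bin if isinstance(c, BorderCall) else int(c) for c in a)
    b_bins = sorted(c.bin if isinstance(c, BorderCall) else int(c) for c in b)
    pairs = [
        (abs(x - y), i, j)
        for i, x in enumerate(a_bins)
        for j, y in enumerate(b_bins)
        if abs(x - y) <= tol_bins
    ]
    pairs.sort()
    used_a, used_b = set(), set()
    matched = 0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched += 1
    return matched, len(a_bins) - matched, len(b_bins) - matched


def _union_intervals(intervals):
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def interval_overlap_kb(a, b):
    """Total kb covered by each interval set and by their intersection.

    Intervals are bp ``(start, end)`` half-open pairs on the same genome;
    each set is unioned before measuring.  Returns ``(a_kb, b_kb,
    intersection_kb)``.
    """
    ua, ub = _union_intervals(a), _union_intervals(b)
    a_bp = sum(e - s for s, e in ua)
    b_bp = sum(e - s for s, e in ub)
    inter_bp = 0
    i = j = 0
    while i < len(ua) and j < len(ub):
        s = max(ua[i][0], ub[j][0])
        e = min(ua[i][1], ub[j][1])
        if e > s:
            inter_bp += e - s
        if ua[i][1] < ub[j][1]:
            i += 1
        else:
            j += 1
    return a_bp / 1000.0, b_bp / 1000.0, inter_bp / 1000.0
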