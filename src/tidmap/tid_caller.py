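"""Bundle (transcription-induced domain) calling along the main diagonal.

TIDs appear in sub-kilobase bacterial Hi-C maps as short stretches of
dense contacts hugging the main diagonal ("bundles").  They are detected
with a template-matching strategy: a small Gaussian kernel shaped like the
bundle motif is convolved with the local image centred on every diagonal
bin, giving a per-bin convolution score; a slowly varying background (the
"second envelope" of the score) is subtracted; peaks of the corrected
score are called and extended sideways until the signal drops below one
third of the peak value.

The kernel of size ``n`` (odd, default 5) is

    M[i, j] = (1/sqrt(2)) * exp(-0.5 * ((|i-j| + |n-1-i-j|) / (2*(n-1)))**2)

with 0-based indices.  It is symmetric about both the main diagonal and
the anti-diagonal and takes its maximum 1/sqrt(2) on the anti-diagonal
(which runs along the map's main diagonal inside the local image).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from tidmap.contact_map import ContactMap

__all__ = [
    "KernelSpec",
    "BundleDomain",
    "bundle_kernel",
    "diagonal_convolution_score",
    "remove_second_envelope",
    "lower_envelope",
    "call_bundles",
]


@dataclass(frozen=True)
class KernelSpec:
    """Bundle-detection convolution kernel (``n x n`` Gaussian template)."""

    n: int
    values: np.ndarray


@dataclass(frozen=True)
class BundleDomain:
    """A called bundle: half-open bin interval with its peak position/score.

    On circular genomes a domain spanning the origin keeps ``end_bin``
    (and possibly ``peak_bin``) beyond ``n_bins`` so the interval stays
    half-open; reduce modulo ``n_bins`` for genomic coordinates.
    """

    start_bin: int
    end_bin: int
    peak_bin: int
    peak_score: float

    def __post_init__(self):
        if not (self.start_bin <= self.peak_bin < self.end_bin):
            raise ValueError("peak_bin must lie inside [start_bin, end_bin)")
        if not self.peak_score > 0:
            raise ValueError("peak_score must be positive")

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


def bundle_kernel(n: int = 5) -> KernelSpec:
    """Build the diagonal-bundle Gaussian kernel of odd size ``n >= 3``."""
    if n < 3 or n % 2 == 0:
        raise ValueError("kernel size must be an odd integer >= 3")
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    arg = (np.abs(i - j) + np.abs(n - 1 - i - j)) / (2.0 * (n - 1))
    values = (1.0 / np.sqrt(2.0)) * np.exp(-0.5 * arg**2)
    return KernelSpec(n=n, values=values)


def diagonal_convolution_score(
    cmap: ContactMap, kernel: KernelSpec | None = None
) -> np.ndarray:
    """Per-bin convolution score of the map against the bundle kernel.

    ``score[i]`` is the elementwise product of the kernel with the
    ``n x n`` local image centred on ``(i, i)``, summed.  Windows wrap on
    circular genomes; on linear genomes edge bins whose window leaves the
    matrix get NaN.  Masked bins contribute zero to the windows of their
    neighbours, and the score at a masked centre bin is NaN.
    """
    if kernel is None:
        kernel = bundle_kernel()
    n = kernel.n
    half = n // 2
    matrix = np.nan_to_num(cmap.matrix.copy())
    bad = list(cmap.mask)
    if bad:
        matrix[bad, :] = 0.0
        matrix[:, bad] = 0.0
    nb = cmap.n_bins
    score = np.full(nb, np.nan)
    offsets = np.arange(-half, half + 1)
    for i in range(nb):
        if i in cmap.mask:
            continue
        idx = i + offsets
        if cmap.circular:
            idx = idx % nb
        elif idx[0] < 0 or idx[-1] >= nb:
            continue
        score[i] = float(np.sum(matrix[np.ix_(idx, idx)] * kernel.values))
    return score


def _local_min_anchors(track: np.ndarray, circular: bool) -> np.ndarray:
    """Indices of (non-strict) local minima; endpoints included when linear."""
    m = len(track)
    left = np.roll(track, 1)
    right = np.roll(track, -1)
    is_min = (track <= left) & (track <= right)
    if not circular:
        is_min[0] = track[0] <= track[1]
        is_min[-1] = track[-1] <= track[-2]
        # linear tracks keep both endpoints as anchors so the envelope is
        # defined everywhere without extrapolation
        is_min[0] = True
        is_min[-1] = True
    anchors = np.flatnonzero(is_min)
    if anchors.size == 0:  # strictly monotone circular track
        anchors = np.array([int(np.argmin(track))])
    return anchors


def lower_envelope(track: np.ndarray, circular: bool = True) -> np.ndarray:
    """Piecewise-linear interpolation through the track's local minima.

    On circular tracks interpolation wraps across the origin; on linear
    tracks the endpoints always anchor the envelope.
    """
    track = np.asarray(track, dtype=float)
    m = len(track)
    anchors = _local_min_anchors(track, circular)
    if not circular:
        return np.interp(np.arange(m), anchors, track[anchors])
    if anchors.size == 1:
        return np.full(m, track[anchors[0]])
    # unwrap the circle at the first anchor and add the wrapped copy of it
    x = np.concatenate([anchors, [anchors[0] + m]])
    y = track[np.concatenate([anchors, anchors[:1]])]
    pos = np.arange(m)
    pos_shift = np.where(pos < anchors[0], pos + m, pos)
    return np.interp(pos_shift, x, y)


def remove_second_envelope(track: np.ndarray, circular: bool = True) -> np.ndarray:
    """Subtract the second lower envelope to flatten regional trends.

    ``E1`` is the piecewise-linear interpolation through the local minima
    of the track and ``E2`` is the same operator applied to ``E1``; the
    returned track is ``track - E2``.  Tracks shorter than 3 bins are
    returned unchanged with a warning.  NaNs (masked score positions) are
    linearly interpolated before the envelope is built and restored to NaN
    afterwards.
    """
    track = np.asarray(track, dtype=float)
    if len(track) < 3:
        warnings.warn("track shorter than 3 bins; envelope removal skipped", stacklevel=2)
        return track.copy()
    nan = ~np.isfinite(track)
    filled = track.copy()
    if np.any(nan):
        if np.all(nan):
            return track.copy()
        idx = np.arange(len(track))
        if circular:
            good = np.flatnonzero(~nan)
            ext_x = np.concatenate([good, good + len(track)])
            ext_y = np.tile(track[good], 2)
            filled[nan] = np.interp(idx[nan] + len(track), ext_x, ext_y)
        else:
            filled[nan] = np.interp(idx[nan], idx[~nan], track[~nan])
    e1 = lower_envelope(filled, circular)
    e2 = lower_envelope(e1, circular)
    corrected = filled - e2
    corrected[nan] = np.nan
    return corrected


def _masked_runs(mask_arr: np.ndarray, min_len: int) -> np.ndarray:
    """Boolean array marking bins inside masked runs of length > min_len."""
    out = np.zeros_like(mask_arr)
    m = len(mask_arr)
    i = 0
    while i < m:
        if mask_arr[i]:
            j = i
            while j < m and mask_arr[j]:
                j += 1
            if j - i > min_len:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def call_bundles(
    corrected: np.ndarray,
    min_size_bins: int = 2,
    circular: bool = True,
    raw_score: np.ndarray | None = None,
    mask: frozenset[int] | None = None,
) -> list[BundleDomain]:
    """Call bundle domains from the envelope-corrected convolution score.

    Peaks are strict local maxima of the corrected track (leftmost bin on
    plateaus) whose height exceeds the median threshold; each peak is
    extended left and right while the corrected score stays at or above
    one third of the peak value, overlapping extensions are merged (the
    merged peak is the maximum), and domains shorter than
    ``min_size_bins`` are dropped.

    When ``raw_score`` is given, the median threshold is the median of the
    raw (pre-envelope-subtraction) convolution score, which measures the
    typical diagonal signal level and so rejects small background
    fluctuations of the flattened track; otherwise the median of the
    corrected track is used.  Medians are taken over defined, unmasked
    bins only.  Extension never crosses a masked run longer than 2 bins.
    """
    corrected = np.asarray(corrected, dtype=float)
    m = len(corrected)
    if m == 0:
        return []
    mask_arr = np.zeros(m, dtype=bool)
    if mask:
        mask_arr[list(mask)] = True
    defined = np.isfinite(corrected) & ~mask_arr
    if not np.any(defined):
        return []
    threshold_track = raw_score if raw_score is not None else corrected
    threshold_defined = np.isfinite(threshold_track) & ~mask_arr
    threshold = float(np.median(np.asarray(threshold_track)[threshold_defined]))

    blocked = _masked_runs(mask_arr | ~np.isfinite(corrected), 2)
    work = np.where(defined, corrected, -np.inf)

    def _get(i: int) -> float:
        return work[i % m] if circular else (work[i] if 0 <= i < m else -np.inf)

    peaks = []
    for i in range(m):
        if not defined[i]:
            continue
        v = work[i]
        if not v > threshold:
            continue
        left, right = _get(i - 1), _get(i + 1)
        # strict local maximum; plateaus take the leftmost bin
        if v > left and v >= right:
            if v == right:
                j = i + 1
                while _get(j) == v:
                    j += 1
                if _get(j) > v:
                    continue
            peaks.append(i)

    domains = []
    for p in peaks:
        peak_val = work[p]
        stop = peak_val / 3.0
        lo = p
        for step in range(1, m):
            i = p - step
            if not circular and i < 0:
                break
            ii = i % m
            if blocked[ii] or not (work[ii] >= stop):
                break
            lo = i
        hi = p
        for step in range(1, m):
            i = p + step
            if not circular and i >= m:
                break
            ii = i % m
            if blocked[ii] or not (work[ii] >= stop):
                break
            hi = i
        if hi + 1 - lo > m:  # extension wrapped the whole circle
            lo, hi = 0, m - 1
        domains.append((lo, hi + 1, p, float(peak_val)))

    merged = _merge_domains(domains, m, circular)
    return [
        BundleDomain(start_bin=s, end_bin=e, peak_bin=p, peak_score=v)
        for s, e, p, v in merged
        if e - s >= min_size_bins
    ]


def _merge_domains(domains, m, circular):
    """Merge overlapping [start, end) extents; merged peak = the higher one."""
    if not domains:
        return []
    # normalize circular wrap-around extents into possibly-beyond-m intervals
    norm = []
    for lo, hi, p, v in domains:
        if lo < 0:
            lo += m
            hi += m
            p_adj = p + m
        else:
            p_adj = p
        norm.append([lo, hi, p_adj, v])
    norm.sort()
    out = [norm[0]]
    for lo, hi, p, v in norm[1:]:
        cur = out[-1]
        if lo < cur[1]:  # overlap
            cur[1] = max(cur[1], hi)
            if v > cur[3]:
                cur[2], cur[3] = p, v
        else:
            out.append([lo, hi, p, v])
    # a wrapped interval may also overlap the first one
    if circular and len(out) > 1:
        first, last = out[0], out[-1]
        if last[1] - m > first[0]:
            first[0] = min(first[0], last[0] - m)
            if last[3] > first[3]:
                first[2], first[3] = last[2] - m, last[3]
            first[1] = max(first[1], last[1] - m)
            out = out[:-1]
    result = []
    for lo, hi, p, v in out:
        # normalize so start lies in [0, m); a domain spanning the origin
        # keeps end_bin (and peak_bin) beyond m to stay half-open
        shift = (lo % m) - lo if circular else 0
        result.append((lo + shift, hi + shift, p + shift, v))
    return result
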