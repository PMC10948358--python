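"""1D genomic-track utilities.

Tracks (RNA-seq CPM, ChIP CPM, polymerase occupancy, short-range Hi-C
signal) live on the same binned, usually circular, genome as the contact
maps.  This module provides binning, z-transformation, the short-range
Hi-C signal (contacts between adjacent bins), circular Gaussian blur
(used for supercoiling ChIP tracks) and Spearman rank correlation
between tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import spearmanr

from tidmap.contact_map import ContactMap

__all__ = [
    "GenomicTrack",
    "bin_track",
    "z_transform",
    "short_range_signal",
    "gaussian_blur_circular",
    "track_spearman",
]


@dataclass
class GenomicTrack:
    """Per-bin signal over a binned genome."""

    values: np.ndarray
    bin_size: int
    genome_length: int
    circular: bool = True
    units: str = "CPM"  # CPM | z | contacts | occupancy
    mask: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n_expected = -(-int(self.genome_length) // int(self.bin_size))
        if len(self.values) != n_expected:
            raise ValueError(
                f"track has {len(self.values)} bins, expected {n_expected}"
            )
        self.mask = frozenset(int(i) for i in self.mask)

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def valid(self) -> np.ndarray:
        ok = np.isfinite(self.values)
        if self.mask:
            ok[list(self.mask)] = False
        return ok


def bin_track(
    values: np.ndarray,
    factor: int,
    aggregator: str = "mean",
    bin_size: int = 1,
    genome_length: int | None = None,
    circular: bool = True,
    units: str = "CPM",
) -> GenomicTrack:
    """Aggregate a fine signal into coarser bins of ``factor`` elements.

    The last partial block is aggregated over its actual length, so a mean
    stays a mean and a sum conserves the total.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if aggregator not in ("mean", "sum"):
        raise ValueError("aggregator must be 'mean' or 'sum'")
    values = np.asarray(values, dtype=float)
    factor = int(factor)
    n_out = -(-len(values) // factor)
    out = np.empty(n_out)
    for c in range(n_out):
        block = values[c * factor : (c + 1) * factor]
        out[c] = block.sum() if aggregator == "sum" else block.mean()
    if genome_length is None:
        genome_length = len(values) * bin_size
    return GenomicTrack(
        values=out,
        bin_size=bin_size * factor,
        genome_length=genome_length,
        circular=circular,
        units=units,
    )


def z_transform(track: GenomicTrack, ddof: int = 1) -> GenomicTrack:
    """Standardize a track to mean 0, sd 1 over its unmasked bins.

    Uses the sample (n-1) standard deviation by default.  Constant or
    nearly empty tracks raise, since a z-score is then undefined.
    """
    ok = track.valid()
    vals = track.values[ok]
    if vals.size < 2:
        raise ValueError("z-transform needs at least 2 unmasked bins")
    sd = vals.std(ddof=ddof)
    if sd == 0:
        raise ValueError("z-transform undefined for a constant track")
    out = np.full_like(track.values, np.nan)
    out[ok] = (vals - vals.mean()) / sd
    return replace(track, values=out, units="z")


def short_range_signal(cmap: ContactMap) -> GenomicTrack:
    """Contacts between adjacent bins: ``value[i] = map[i, i+1]``.

    Wraps at the end of circular genomes; a value is masked when either
    bin of the pair is masked.  Conventionally computed on the balanced
    5-kb map, but any binning is accepted.
    """
    n = cmap.n_bins
    nxt = np.roll(np.arange(n), -1)
    values = cmap.matrix[np.arange(n), nxt].astype(float)
    masked = cmap.mask_array()
    pair_masked = masked | masked[nxt]
    if not cmap.circular:
        values[-1] = np.nan
    values[pair_masked] = np.nan
    return GenomicTrack(
        values=values,
        bin_size=cmap.bin_size,
        genome_length=cmap.genome_length,
        circular=cmap.circular,
        units="contacts",
        mask=frozenset(np.flatnonzero(pair_masked)),
    )


def gaussian_blur_circular(
    track: GenomicTrack, sigma_bp: float = 2500.0
) -> GenomicTrack:
    """Wrapped Gaussian smoothing of a track; total signal is conserved.

    ``sigma_bp`` is expressed in bp and converted to bins by the track's
    bin size (2,500 bp is the conventional width for supercoiling ChIP
    signal at 1-bp resolution).  The kernel is truncated at 4 sigma.  On
    linear tracks reflective boundaries are used instead of wrapping.
    """
    if sigma_bp <= 0:
        raise ValueError("sigma_bp must be positive")
    sigma_bins = sigma_bp / track.bin_size
    mode = "wrap" if track.circular else "reflect"
    blurred = gaussian_filter1d(track.values, sigma=sigma_bins, mode=mode, truncate=4.0)
    return replace(track, values=blurred)


def track_spearman(a: GenomicTrack, b: GenomicTrack) -> float:
    """Spearman rank correlation between two tracks on common unmasked bins.

    Ties receive average ranks.  Requires at least 3 common bins; returns
    NaN when either track is constant over the common support.
    """
    if a.bin_size != b.bin_size or a.n_bins != b.n_bins:
        raise ValueError("tracks must share binning")
    ok = a.valid() & b.valid()
    if ok.sum() < 3:
        raise ValueError("need at least 3 common unmasked bins")
    x, y = a.values[ok], b.values[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = spearmanr(x, y)
    return float(rho)
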