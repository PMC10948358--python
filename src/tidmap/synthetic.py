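"""Seeded synthetic genomes, tracks and Hi-C maps for end-to-end testing.

The generator emulates the statistical structure of sub-kilobase
bacterial Hi-C experiments together with matched RNA-seq and
polymerase-ChIP tracks:

* a circular genome binned at 0.5-5 kb with a power-law contact decay
  ``p(s) ~ (s + s0) ** -alpha``;
* a non-overlapping transcription-unit (gene/operon) layout with
  log-normal expression; the top 10% most expressed TUs are "active";
* a polymerase occupancy track proportional to expression inside TUs,
  scaled to a true maximum occupancy ``epsilon_true``, optionally with a
  single strong T7-like unit whose occupancy decays exponentially along
  a ~115-kb transcription track;
* contact counts that follow the occupancy-insulation (variant-2) model
  weights, a short-range "plaid" enrichment between active bins, Poisson
  sequencing noise at a configurable depth, and randomly masked
  low-coverage ("white line") bins;
* optionally, large block domains (CID-like) for boundary-caller tests.

Everything is reproducible bit-for-bit from the scenario seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from tidmap.contact_map import ContactMap, DistanceDecay, write_map
from tidmap.pileup import Gene, select_active_genes
from tidmap.polymerase_model import OccupancyTrack, model_weights

__all__ = [
    "T7Unit",
    "SyntheticScenario",
    "make_scenario",
    "simulate_occupancy",
    "expected_matrix",
    "simulate_map",
    "true_tid_intervals",
    "write_fixture",
]


@dataclass(frozen=True)
class T7Unit:
    """A single rifampicin-insensitive T7-polymerase transcription unit."""

    position_bp: int  # promoter position
    direction: int = 1  # +1 rightwards, -1 leftwards
    track_length_bp: int = 115_000
    decay_bp: float = 40_000.0  # exponential decay length of occupancy


@dataclass
class SyntheticScenario:
    """A fully specified synthetic experiment (genome, tracks, map model)."""

    genome_length: int = 1_000_000
    bin_size: int = 1000
    circular: bool = True
    n_genes: int = 100
    tu_length_range_bp: tuple[int, int] = (1000, 20_000)
    expression_mu: float = np.log(50.0)  # log-normal RPKM parameters
    expression_sigma: float = 1.5
    active_fraction: float = 0.10
    epsilon_true: float = 0.15
    decay_exponent: float = 0.8
    decay_s0_bins: float = 1.0
    plaid_kappa: float = 8.0
    plaid_range_bp: int = 25_000
    sequencing_depth: int = 2_000_000
    white_line_bins: int = 5
    rifampicin: bool = False
    t7_unit: T7Unit | None = None
    domain_boundaries_bp: tuple[int, ...] = ()  # optional CID-like blocks
    domain_boost: float = 0.0
    seed: int = 0
    gene_layout: list[Gene] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return -(-self.genome_length // self.bin_size)

    def distance_decay(self) -> DistanceDecay:
        """The scenario's ground-truth p(s) (arbitrary scale)."""
        s_max = self.n_bins // 2 if self.circular else self.n_bins - 1
        s = np.arange(s_max + 1)
        values = (s + self.decay_s0_bins) ** (-self.decay_exponent)
        return DistanceDecay(separations=s, values=values, bin_size=self.bin_size)

    def active_genes(self) -> list[Gene]:
        expressed = [g for g in self.gene_layout if g.expression > 0]
        if not expressed:
            return []
        return select_active_genes(expressed, self.active_fraction)

    def active_bin_indicator(self) -> np.ndarray:
        """1.0 at bins overlapping an active TU (or the T7 track), else 0."""
        a = np.zeros(self.n_bins)
        for g in self.active_genes():
            a[self._bins_of(g.start, g.end)] = 1.0
        if self.t7_unit is not None:
            a[self._t7_bins()] = 1.0
        return a

    def _bins_of(self, start_bp: int, end_bp: int) -> np.ndarray:
        b0 = start_bp // self.bin_size
        b1 = -(-end_bp // self.bin_size)
        idx = np.arange(b0, b1)
        return idx % self.n_bins if self.circular else idx[(idx >= 0) & (idx < self.n_bins)]

    def _t7_bins(self) -> np.ndarray:
        t7 = self.t7_unit
        if t7.direction >= 0:
            return self._bins_of(t7.position_bp, t7.position_bp + t7.track_length_bp)
        return self._bins_of(t7.position_bp - t7.track_length_bp + 1, t7.position_bp + 1)


def make_scenario(seed: int = 0, **config) -> SyntheticScenario:
    """Sample a reproducible scenario: gene layout plus expression levels.

    TU lengths are drawn log-uniformly over ``tu_length_range_bp`` (operon
    lengths skew short), placed without overlap with random intergenic
    gaps and random strands, and expression is log-normal.  Under
    ``rifampicin=True`` every native TU's expression is set to zero, so
    only an optional T7 unit remains transcribed.  Raises when the
    requested genes cannot fit in the genome.
    """
    scenario = SyntheticScenario(seed=seed, **config)
    if scenario.n_genes == 0:
        return scenario
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    lo, hi = scenario.tu_length_range_bp
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), scenario.n_genes))
    lengths = np.maximum(lengths.astype(int), 1)
    total = int(lengths.sum())
    free = scenario.genome_length - total
    if free < scenario.n_genes:  # need at least ~1 bp between TUs
        raise ValueError(
            f"cannot fit {scenario.n_genes} TUs totalling {total} bp in a "
            f"{scenario.genome_length} bp genome"
        )
    gaps = rng.multinomial(free - scenario.n_genes, np.full(scenario.n_genes, 1 / scenario.n_genes))
    gaps = gaps + 1
    strands = rng.choice(["+", "-"], scenario.n_genes)
    expression = rng.lognormal(scenario.expression_mu, scenario.expression_sigma,
                               scenario.n_genes)
    if scenario.rifampicin:
        expression = np.zeros(scenario.n_genes)
    genes = []
    pos = int(rng.integers(0, scenario.bin_size))
    for k in range(scenario.n_genes):
        pos += int(gaps[k])
        start, end = pos, pos + int(lengths[k])
        genes.append(
            Gene(id=f"tu{k:04d}", start=start, end=end, strand=str(strands[k]),
                 expression=float(expression[k]))
        )
        pos = end
    scenario.gene_layout = genes
    return scenario


def simulate_occupancy(scenario: SyntheticScenario) -> OccupancyTrack:
    """Per-bin polymerase occupancy implied by the scenario.

    Occupancy is proportional to expression inside active TUs and zero
    elsewhere; an optional T7 unit contributes an exponentially decaying
    track from its promoter in its direction.  The final track is scaled
    so its maximum equals ``epsilon_true`` (an all-silent scenario stays
    identically zero).
    """
    c = np.zeros(scenario.n_bins)
    for g in scenario.active_genes():
        c[scenario._bins_of(g.start, g.end)] = np.maximum(
            c[scenario._bins_of(g.start, g.end)], g.expression
        )
    t7 = scenario.t7_unit
    if t7 is not None:
        bins = scenario._t7_bins()
        # distance of each track bin from the promoter, in bp
        dist = np.arange(len(bins)) * scenario.bin_size
        if t7.direction < 0:
            dist = dist[::-1]
        shape = np.exp(-dist / t7.decay_bp)
        peak = c.max() if c.max() > 0 else 1.0
        c[bins] = np.maximum(c[bins], shape * peak)
    if c.max() > 0:
        c = c * (scenario.epsilon_true / c.max())
    return OccupancyTrack(values=c, epsilon=scenario.epsilon_true)


def expected_matrix(scenario: SyntheticScenario) -> np.ndarray:
    """Expected (pre-noise) contact matrix, scaled to the sequencing depth.

    ``E[i, j] = p(s_ij) * w2(i, j) * (1 + kappa * a_i * a_j * [s_ij <= r])``
    with ``w2`` the occupancy-insulation model weights, ``a`` the
    active-bin indicator and ``r`` the plaid range; optional block domains
    multiply within-domain pairs by ``1 + domain_boost``.  Scaled so the
    upper triangle (diagonal counted once) sums to ``sequencing_depth``.
    """
    n = scenario.n_bins
    p = scenario.distance_decay()
    occ = simulate_occupancy(scenario)
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    d = np.abs(i - j)
    if scenario.circular:
        d = np.minimum(d, n - d)
    expected = p(d) * model_weights(occ.values, 2, scenario.circular)
    if scenario.plaid_kappa > 0:
        a = scenario.active_bin_indicator()
        within = d <= scenario.plaid_range_bp // scenario.bin_size
        expected *= 1.0 + scenario.plaid_kappa * np.outer(a, a) * within
    if scenario.domain_boost > 0 and scenario.domain_boundaries_bp:
        bounds = sorted(b // scenario.bin_size for b in scenario.domain_boundaries_bp)
        dom = np.zeros(n, dtype=int)
        for k, b in enumerate(bounds):
            dom[b:] = k + 1
        dom[dom == len(bounds)] = 0 if scenario.circular else len(bounds)
        same = dom[:, None] == dom[None, :]
        expected *= np.where(same, 1.0 + scenario.domain_boost, 1.0)
    iu = np.triu_indices(n)
    expected *= scenario.sequencing_depth / expected[iu].sum()
    return expected


def simulate_map(scenario: SyntheticScenario) -> ContactMap:
    """Poisson-sampled raw contact map with masked white-line bins."""
    expected = expected_matrix(scenario)
    n = scenario.n_bins
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    iu, ju = np.triu_indices(n)
    counts = np.zeros((n, n))
    sampled = rng.poisson(expected[iu, ju]).astype(float)
    counts[iu, ju] = sampled
    counts = counts + np.triu(counts, 1).T
    mask = set()
    if scenario.white_line_bins > 0:
        wl = rng.choice(n, size=scenario.white_line_bins, replace=False)
        counts[wl, :] = 0.0
        counts[:, wl] = 0.0
        mask = set(int(b) for b in wl)
    return ContactMap(
        matrix=counts,
        bin_size=scenario.bin_size,
        genome_length=scenario.genome_length,
        circular=scenario.circular,
        mask=frozenset(mask),
        balanced=False,
    )


def true_tid_intervals(scenario: SyntheticScenario) -> list[tuple[int, int]]:
    """bp intervals of the planted TIDs (active TUs plus any T7 track)."""
    intervals = [(g.start, g.end) for g in scenario.active_genes()]
    t7 = scenario.t7_unit
    if t7 is not None:
        if t7.direction >= 0:
            intervals.append((t7.position_bp, t7.position_bp + t7.track_length_bp))
        else:
            intervals.append((t7.position_bp - t7.track_length_bp + 1, t7.position_bp + 1))
    return sorted(intervals)


def _write_bedgraph(path, values, bin_size, name):
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={name}\n")
        for k, v in enumerate(values):
            fh.write(f"genome\t{k * bin_size}\t{(k + 1) * bin_size}\t{v:.6g}\n")


def write_fixture(scenario: SyntheticScenario, outdir: str) -> dict:
    """Write the scenario's map, tracks, genes and truth tables to disk.

    Emits ``matrix.tsv`` (triplet), ``genes.bed`` (BED6 + RPKM),
    ``rna_cpm.bedgraph``, ``occupancy.bedgraph`` and ``truth.json``
    (planted TID intervals, domain boundaries, epsilon_true, seed and
    the full scenario configuration).  Returns the path mapping.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "matrix": os.path.join(outdir, "matrix.tsv"),
        "genes": os.path.join(outdir, "genes.bed"),
        "rna": os.path.join(outdir, "rna_cpm.bedgraph"),
        "occupancy": os.path.join(outdir, "occupancy.bedgraph"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_map(simulate_map(scenario), paths["matrix"], format="triplet")
    with open(paths["genes"], "w") as fh:
        for g in scenario.gene_layout:
            fh.write(f"genome\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\t{g.expression:.6g}\n")
    rna = np.zeros(scenario.n_bins)
    for g in scenario.gene_layout:
        bins = scenario._bins_of(g.start, g.end)
        rna[bins] = np.maximum(rna[bins], g.expression)
    _write_bedgraph(paths["rna"], rna, scenario.bin_size, "rna_cpm")
    occ = simulate_occupancy(scenario)
    _write_bedgraph(paths["occupancy"], occ.values, scenario.bin_size, "occupancy")
    config = asdict(scenario)
    config.pop("gene_layout")
    truth = {
        "tid_intervals_bp": true_tid_intervals(scenario),
        "domain_boundaries_bp": list(scenario.domain_boundaries_bp),
        "epsilon_true": scenario.epsilon_true,
        "seed": scenario.seed,
        "config": config,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return paths
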