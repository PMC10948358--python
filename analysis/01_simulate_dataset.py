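"""Generate the reference synthetic dataset used by the downstream analyses.

Two scenarios are written under results/dataset/:

* ``tids/`` — a 3-Mb circular genome with 200 transcription units of
  1-20 kb, the top 10% most expressed being active; contact counts carry
  a ~3x short-range enrichment (after balancing) inside and between
  nearby active units, Poisson noise at 2M contacts per Mb, and 5
  masked low-coverage bins.
* ``t7/`` — a transcription-silenced (rifampicin) 1-Mb genome carrying a
  single strong T7-like unit with a 115-kb exponentially decaying
  occupancy track, used for the occupancy-model fits.

Each directory contains the sparse contact matrix, gene table, RNA and
occupancy bedgraphs, and a truth table (planted TID intervals, true
maximum occupancy, full config) for later comparison.
"""

import pathlib
import sys

from tidmap import synthetic as syn

SEED = 3
OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "dataset"


def main():
    tids = syn.make_scenario(seed=SEED, genome_length=3_000_000, n_genes=200,
                             sequencing_depth=6_000_000)
    paths = syn.write_fixture(tids, str(OUT / "tids"))
    print(f"TID scenario: {len(tids.gene_layout)} TUs, "
          f"{len(tids.active_genes())} active (planted TIDs), "
          f"{tids.sequencing_depth:.0f} expected contacts")
    print("  wrote", ", ".join(sorted(paths)))

    t7 = syn.make_scenario(seed=SEED + 100, genome_length=1_000_000,
                           n_genes=0, rifampicin=True, plaid_kappa=0.0,
                           epsilon_true=0.15,
                           t7_unit=syn.T7Unit(position_bp=300_000))
    paths = syn.write_fixture(t7, str(OUT / "t7"))
    occ = syn.simulate_occupancy(t7)
    print(f"T7 scenario: occupancy peak {occ.values.max():.2f} at bin "
          f"{occ.values.argmax()}, track covers "
          f"{(occ.values > 0).sum()} kb")
    print("  wrote", ", ".join(sorted(paths)))

    # same T7 unit but with the short-range bundling term active, for the
    # track-correlation analysis (the model fit needs the plaid-free map)
    t7b = syn.make_scenario(seed=SEED + 100, genome_length=1_000_000,
                            n_genes=0, rifampicin=True, epsilon_true=0.15,
                            t7_unit=syn.T7Unit(position_bp=300_000))
    paths = syn.write_fixture(t7b, str(OUT / "t7_bundle"))
    print("T7 bundle scenario: short-range enrichment over the track")
    print("  wrote", ", ".join(sorted(paths)))
    return 0


if __name__ == "__main__":
    sys.exit(main())
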