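# tidmap

Detection and modeling of **transcription-induced domains (TIDs)** in
sub-kilobase bacterial Hi-C contact maps.

High-resolution (0.5–1 kb) Hi-C maps of bacteria such as *E. coli* show
hundreds of short (1–20 kb) squares of dense contacts hugging the main
diagonal — "bundled" domains that coincide with actively transcribed
units and disappear when transcription is blocked. `tidmap` implements
the complete matrix-level analysis behind this observation for people
working with bacterial (or other small, circular-genome) Hi-C data:

* **contact-map preprocessing** — dense/sparse text I/O, ICE balancing,
  rebinning, downsampling to matched depth, log2 map comparison,
  distance decay *p(s)*, and masking of low-coverage "white line" bins
  (below median − 3·MAD of per-bin coverage);
* **bundle (TID) calling** — convolution of the diagonal with a
  Gaussian template kernel
  `M[i,j] = (1/√2)·exp(−½·[(|i−j| + |n−1−i−j|)/(2(n−1))]²)`
  (n = 5), removal of the second lower envelope of the score, peak
  calling, and extension of each peak until the signal drops below one
  third of its height;
* **domain-boundary calling** — a directionality index (paired t-test
  between each bin's left and right correlation vectors, boundaries at
  significant negative→positive transitions, |t| ≥ 2) and a
  multi-window relative insulation score
  `RI = (A + B − C)/(A + B + C)` averaged over 10–30 kb windows;
* **gene-anchored pileups** — strand-oriented averaging of 50-kb map
  windows centred on the start codons of the most transcribed
  transcription units, with a jittered-anchor ratio control;
* **polymerase-occupancy contact models** — two generative models in
  which a fraction `C_i ∈ [0, ε]` of contacts at each bin is mediated
  by RNA polymerase: variant 1 (`w = C_iC_j + (1−C_i)(1−C_j)`) and
  variant 2, which adds a polymerase-train interaction term through
  `m = Σ C_n` over intervening bins (`w = m·C_iC_j + (1−C_i)(1−C_j)`);
  the single parameter ε (maximum occupancy) is fitted on a grid,
  by Poisson likelihood of the raw counts by default, with the
  classical Spearman-correlation scoring also available and reported;
* **track utilities** — short-range Hi-C signal (adjacent-bin
  contacts), z-transforms, circular Gaussian blur (σ = 2,500 bp, as
  applied to supercoiling ChIP signal), Spearman track correlations;
* **a synthetic-data generator** — seeded circular genomes with
  TU layouts, log-normal expression, occupancy tracks (including a
  T7-like unit), power-law distance decay, plaid enrichment between
  active regions, Poisson sequencing noise and masked bins, so the
  entire pipeline runs and is tested without any external data.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate_dataset.py
python analysis/02_call_bundles.py
```

prints

```
TID scenario: 200 TUs, 20 active (planted TIDs), 6000000 expected contacts
called 20 bundles covering 205 kb (sizes 3-21 kb)
planted-TID recovery: recall 1.00, precision 1.00 at 50% reciprocal overlap
```

i.e. on a 3-Mb genome whose 20 most-expressed transcription units carry
a ~3× short-range contact enrichment, the kernel caller recovers every
planted TID with no false calls (matching at 50% reciprocal overlap).
`03_call_borders.py` scores both boundary callers against 8 planted
block domains (insulation F1 0.94 at 1-kb resolution, DI F1 1.00 at
5 kb); `04_pileup_analysis.py` shows the TSS-anchored pileup ratio is
enriched ~2.2× at the centre and flat (~1.0) away from it, with the
diagonal profile tracking averaged transcription at Pearson r = 0.97;
`05_fit_polymerase_model.py` recovers the planted maximum occupancy
ε = 0.15 for both model variants; `06_track_correlations.py` reports
Spearman ≈ 0.55 between short-range contacts and the polymerase
occupancy track around a T7-like unit.

The same operations are available as a library:

```python
from tidmap import synthetic as syn
from tidmap.contact_map import ice_balance
from tidmap import tid_caller as tc

scenario = syn.make_scenario(seed=3, genome_length=3_000_000,
                             n_genes=200, sequencing_depth=6_000_000)
balanced = ice_balance(syn.simulate_map(scenario))
score = tc.diagonal_convolution_score(balanced)
corrected = tc.remove_second_envelope(score)
bundles = tc.call_bundles(corrected, raw_score=score, mask=balanced.mask)
```

or through the orchestrator `tidmap.pipeline.run_pipeline(config)`,
which executes the configured stages in order and returns a
JSON-serializable report.

## Layout

```
src/tidmap/          library (contact_map, tid_caller, border_callers,
                     pileup, polymerase_model, tracks, synthetic, pipeline)
analysis/            numbered narrative drivers over the library
tests/               unit, property and acceptance test suites
scripts/acceptance.py  recompute-everything entry point
docs/methods.md      model and algorithm documentation
```
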